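"""Mutational-signature spectra and constrained maximum-likelihood fitting.

Each tumor's somatic SNVs are summarized as a 96-bin spectrum (pyrimidine
substitution type x flanking bases).  A fixed catalog of signature profiles
(96 x S column-stochastic matrix) is fitted to the spectrum by maximizing
the multinomial likelihood over the exposure simplex with an
expectation-maximization update — monotone in likelihood and derivative
free.  Uncertainty comes from a bootstrap over the SNV set (multinomial
resampling of the spectrum), and a two-stage select-and-refit procedure
first fits the full catalog, keeps signatures whose bootstrap interval
excludes zero and whose point weight clears a minimum, then refits the
selected subset for sharper estimates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import islice as itertools_islice, permutations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .contexts import CONTEXT_LABELS, context_index
from .genome import GenomeModel

logger = logging.getLogger(__name__)

#: Weights below this are snapped to exactly zero after convergence.
_WEIGHT_FLOOR = 1e-6


@dataclass
class SignatureCatalog:
    """96 x S column-stochastic matrix of signature profiles."""

    names: list[str]
    matrix: np.ndarray  # (96, S)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != 96:
            raise ValueError("catalog matrix must be 96 x S")
        if self.matrix.shape[1] != len(self.names):
            raise ValueError("number of names does not match matrix columns")
        if np.any(self.matrix < 0):
            raise ValueError("catalog entries must be non-negative")
        colsums = self.matrix.sum(axis=0)
        if np.any(np.abs(colsums - 1) > 1e-6):
            raise ValueError("every catalog column must sum to 1 (tol 1e-6)")

    @property
    def n_signatures(self) -> int:
        return self.matrix.shape[1]

    def subset(self, names: list[str]) -> "SignatureCatalog":
        idx = [self.names.index(n) for n in names]
        return SignatureCatalog(names=list(names), matrix=self.matrix[:, idx])

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.matrix, index=list(CONTEXT_LABELS), columns=self.names)
        df.index.name = "context"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SignatureCatalog":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if list(df.index) != list(CONTEXT_LABELS):
            raise ValueError(
                f"{path}: rows must be the 96 context labels in canonical order"
            )
        return cls(names=[str(c) for c in df.columns], matrix=df.to_numpy())


@dataclass
class ExposureEstimate:
    signatures: list[str]
    weights: np.ndarray
    lower: np.ndarray  # bootstrap 2.5th percentile
    upper: np.ndarray  # bootstrap 97.5th percentile
    selected: np.ndarray | None = None  # bool, filled by select_and_refit
    n_mutations: int = 0
    log_likelihood: float = float("nan")

    def as_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "signature": self.signatures,
                "weight": self.weights,
                "lo": self.lower,
                "hi": self.upper,
            }
        )
        if self.selected is not None:
            df["selected"] = self.selected
        return df


def synthetic_catalog(
    n_signatures: int = 30, seed: int = 2019, concentration: float = 0.3
) -> SignatureCatalog:
    """A synthetic signature catalog (Dirichlet columns), for tests and demos.

    Profiles are sparse-ish (small Dirichlet concentration) so distinct
    signatures are distinguishable, like real mutational processes.  This is
    NOT a redistributed reference catalog; values are synthetic.
    """
    rng = np.random.default_rng([seed, 0x516])
    mat = rng.dirichlet(np.full(96, concentration), size=n_signatures).T
    names = [f"SBS_S{i + 1:02d}" for i in range(n_signatures)]
    return SignatureCatalog(names=names, matrix=mat)


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------


def spectrum_from_records(records) -> np.ndarray:
    """96-bin spectrum from (ref, alt, five_prime, three_prime) tuples."""
    counts = np.zeros(96, dtype=int)
    for ref, alt, five, three in records:
        counts[context_index(ref, alt, five, three)] += 1
    return counts


def spectrum_96(variants, genome: GenomeModel) -> np.ndarray:
    """96-bin spectrum of somatic SNVs resolved against the reference genome.

    ``variants`` is an iterable with chrom/pos/ref/alt (1-based positions).
    Purine-reference SNVs are reverse-complemented (substitution and flanks)
    by the context machinery; the bin total equals the SNV count.
    """
    counts = np.zeros(96, dtype=int)
    for v in variants:
        pos0 = v.pos - 1
        try:
            tri = genome.trinucleotide(v.chrom, pos0)
        except ValueError as exc:
            raise ValueError(
                f"variant {v.chrom}:{v.pos} {v.ref}>{v.alt}: {exc}"
            ) from None
        if tri[1] != v.ref:
            raise ValueError(
                f"variant {v.chrom}:{v.pos}: ref {v.ref} does not match genome {tri[1]}"
            )
        counts[context_index(v.ref, v.alt, tri[0], tri[2])] += 1
    return counts


def spectra_per_tumor(
    somatic_sets: dict, genome: GenomeModel
) -> pd.DataFrame:
    """Spectrum per patient as a tidy frame (rows: context, cols: patient)."""
    data = {
        patient: spectrum_96(ss.variants, genome)
        for patient, ss in sorted(somatic_sets.items())
    }
    df = pd.DataFrame(data, index=list(CONTEXT_LABELS))
    df.index.name = "context"
    return df


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _log_likelihood(counts: np.ndarray, probs: np.ndarray) -> float:
    mask = counts > 0
    return float(counts[mask] @ np.log(probs[mask]))


def _em_fit(
    counts: np.ndarray,
    matrix: np.ndarray,
    start: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> tuple[np.ndarray, float]:
    """EM for exposure weights of a fixed-component multinomial mixture."""
    n, s = counts.sum(), matrix.shape[1]
    if n < 1:
        raise ValueError("spectrum must contain at least one mutation")
    e = np.full(s, 1.0 / s) if start is None else start.copy()
    for _ in range(max_iter):
        probs = matrix @ e
        # responsibility-weighted reassignment of each bin's counts
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(probs > 0, counts / probs, 0.0)
        e_new = e * (matrix.T @ ratio) / n
        e_new /= e_new.sum()
        if np.max(np.abs(e_new - e)) < tol:
            e = e_new
            break
        e = e_new
    e = np.where(e < _WEIGHT_FLOOR, 0.0, e)
    e /= e.sum()
    return e, _log_likelihood(counts, matrix @ e)


def fit_exposures(
    spectrum: np.ndarray,
    catalog: SignatureCatalog,
    n_bootstrap: int = 1000,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> ExposureEstimate:
    """Maximum-likelihood exposures of a catalog on one spectrum.

    Bootstrap intervals are percentile intervals over multinomial resamples
    of the SNV set (each resample refit from the point estimate).
    Deterministic given ``seed``.
    """
    counts = np.asarray(spectrum, dtype=float)
    if counts.shape != (96,):
        raise ValueError(
            f"spectrum/catalog dimension mismatch: spectrum has shape {counts.shape}"
        )
    n = int(counts.sum())
    if n < 1:
        raise ValueError("spectrum total must be >= 1")
    weights, ll = _em_fit(counts, catalog.matrix, tol=tol, max_iter=max_iter)
    rng = np.random.default_rng([seed, 0xB001])
    boots = np.empty((n_bootstrap, catalog.n_signatures))
    p = counts / n
    warm = np.where(weights > 0, weights, _WEIGHT_FLOOR)
    warm /= warm.sum()
    for b in range(n_bootstrap):
        resampled = rng.multinomial(n, p).astype(float)
        boots[b], _ = _em_fit(
            resampled, catalog.matrix, start=warm, tol=max(tol, 1e-6), max_iter=2000
        )
    lower = np.percentile(boots, 2.5, axis=0)
    upper = np.percentile(boots, 97.5, axis=0)
    return ExposureEstimate(
        signatures=list(catalog.names),
        weights=weights,
        lower=lower,
        upper=upper,
        n_mutations=n,
        log_likelihood=ll,
    )


def select_and_refit(
    spectrum: np.ndarray,
    catalog: SignatureCatalog,
    threshold: float = 0.05,
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> ExposureEstimate:
    """Two-stage fit: full catalog, then refit of the active signatures.

    Stage 1 fits all catalog signatures; a signature is selected iff its
    bootstrap lower bound is strictly positive and its point weight is at
    least ``threshold``.  Stage 2 refits only the selected subset (weights
    renormalized over it).  If nothing is selected, the single best-weight
    signature is kept, with a warning.
    """
    stage1 = fit_exposures(
        spectrum, catalog, n_bootstrap=n_bootstrap, seed=seed
    )
    selected_mask = (stage1.lower > 0) & (stage1.weights >= threshold)
    if not selected_mask.any():
        best = int(np.argmax(stage1.weights))
        logger.warning(
            "no signature passed selection; falling back to best-weight "
            "signature %s", catalog.names[best],
        )
        selected_mask[best] = True
    selected_names = [n for n, m in zip(catalog.names, selected_mask) if m]
    sub = catalog.subset(selected_names)
    stage2 = fit_exposures(spectrum, sub, n_bootstrap=n_bootstrap, seed=seed + 1)
    # report on the full catalog axis, zeros for unselected signatures
    weights = np.zeros(catalog.n_signatures)
    lower = np.zeros(catalog.n_signatures)
    upper = np.zeros(catalog.n_signatures)
    for name, w, lo, hi in zip(
        stage2.signatures, stage2.weights, stage2.lower, stage2.upper
    ):
        i = catalog.names.index(name)
        weights[i], lower[i], upper[i] = w, lo, hi
    return ExposureEstimate(
        signatures=list(catalog.names),
        weights=weights,
        lower=lower,
        upper=upper,
        selected=selected_mask,
        n_mutations=stage2.n_mutations,
        log_likelihood=stage2.log_likelihood,
    )


# ---------------------------------------------------------------------------
# exposure-covariate correlation
# ---------------------------------------------------------------------------


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for Spearman rho by full enumeration."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = len(rx)
    mx, my = rx.mean(), ry.mean()
    sx = np.sqrt(((rx - mx) ** 2).sum())
    sy = np.sqrt(((ry - my) ** 2).sum())
    # rho is a monotone affine function of sum(rx * ry_perm) given fixed ranks;
    # enumerate all n! pairings in memory-bounded chunks
    n_total = 0
    n_extreme = 0
    perm_iter = permutations(ry)
    chunk = 200_000
    while True:
        flat = np.fromiter(
            (v for tup in itertools_islice(perm_iter, chunk) for v in tup),
            dtype=float,
        )
        if flat.size == 0:
            break
        block = flat.reshape(-1, n)
        sxy = block @ rx
        rhos = (sxy - n * mx * my) / (sx * sy)
        n_extreme += int(np.sum(np.abs(rhos) >= abs(rho_obs) - 1e-12))
        n_total += block.shape[0]
    return n_extreme / n_total


def exposure_covariate_correlation(
    exposures, covariate, exact_max_n: int = 10
) -> tuple[float, float]:
    """Spearman rank correlation between per-tumor exposures and a covariate.

    Exact permutation p (full enumeration over rank pairings) for
    n <= ``exact_max_n``; the large-sample t approximation otherwise.
    """
    x = np.asarray(exposures, dtype=float)
    y = np.asarray(covariate, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("exposures and covariate must be equal-length vectors")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(y) == 0 or np.ptp(x) == 0:
        raise ValueError("constant input: Spearman rho undefined")
    rho = float(stats.spearmanr(x, y).statistic)
    if n <= exact_max_n:
        p = _spearman_exact_p(x, y, rho)
    else:
        p = float(stats.spearmanr(x, y).pvalue)
    return rho, p
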
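"""Trinucleotide-context-corrected dN/dS estimation on somatic SNVs.

The estimator asks whether tumors accumulate amino-acid-changing
substitutions faster or slower than expected under neutrality, given the
mutational process.  Context-specific mutation rates are learned from
*synonymous* substitutions (assumed neutral) relative to their mutational
opportunities, and the expected nonsynonymous count under neutrality is the
rate-weighted sum of nonsynonymous opportunities.  dN/dS is then observed /
expected; departures from 1 are tested with a Poisson likelihood-ratio test
and bracketed with a profile-likelihood confidence interval.

This is deliberately lighter than covariate-based cancer selection models:
no gene-level negative-binomial dispersion, no covariates.  It supports the
two outputs the downstream analysis needs — an exome-wide ratio with a
neutrality test, and per-gene ratios using exome-wide rates with gene-local
opportunities.

Rate classes: each of the 96 trinucleotide substitution classes keeps its
own rate when it has at least ``min_obs`` observed synonymous mutations;
sparse classes within the same pyrimidine substitution type share a pooled
rate.  Pooling all the way down to 6 types would erase exactly the context
structure (e.g. CpG C>T enrichment) that motivates the correction, so the
pooling is hierarchical, deterministic and recorded in the estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from scipy import stats
from scipy.optimize import brentq

from .annotate import annotate
from .contexts import BASES, complement, context_index
from .genome import GenomeModel

EFFECTS = ("synonymous", "missense", "nonsense")
_EFFECT_COL = {e: i for i, e in enumerate(EFFECTS)}


def _codon_map() -> dict[str, str]:
    t = CodonTable.unambiguous_dna_by_id[1]
    m = dict(t.forward_table)
    for stop in t.stop_codons:
        m[stop] = "*"
    return m


CODON_AA = _codon_map()


def _classify(ref_codon: str, alt_codon: str) -> str:
    ref_aa, alt_aa = CODON_AA[ref_codon], CODON_AA[alt_codon]
    if alt_aa == ref_aa:
        return "synonymous"
    if alt_aa == "*" and ref_aa != "*":
        return "nonsense"
    return "missense"  # stop-loss binned as missense


@dataclass
class OpportunityTable:
    """Counts of possible coding single-base changes by context and effect.

    ``exome`` and each per-gene entry are (96, 3) arrays with columns
    (synonymous, missense, nonsense); rows follow the canonical 96-context
    order.  Every coding base contributes exactly 3 changes.
    """

    exome: np.ndarray
    per_gene: dict[str, np.ndarray]
    coding_bases: int

    def __post_init__(self) -> None:
        if self.exome.shape != (96, 3):
            raise ValueError("exome opportunity array must be 96 x 3")
        if int(self.exome.sum()) != 3 * self.coding_bases:
            raise ValueError("opportunities must sum to 3 x coding bases")


@dataclass
class DndsEstimate:
    scope: str  # 'exome-wide' or a gene_id
    n_syn: int
    n_mis: int
    n_non: int
    ratio_mis: float | None
    ratio_trunc: float | None
    ratio_all: float | None
    ci_all: tuple[float, float] | None
    p_value: float | None
    pooled_classes: int = 0

    @property
    def defined(self) -> bool:
        return self.ratio_all is not None


def enumerate_coding_changes(genome: GenomeModel) -> pd.DataFrame:
    """Enumerate every possible coding single-base change of the exome.

    One row per (coding position, alternate base): chrom, pos (1-based),
    ref, alt (genomic strand), gene_id, context (0..95) and effect.  This is
    both the substrate of opportunity counting and a sampling frame for
    simulating somatic mutation under arbitrary context-dependent rates.
    """
    rows_chrom: list[str] = []
    rows = {k: [] for k in ("pos", "ref", "alt", "gene_id", "context", "effect")}
    for gene in genome.genes:
        seq = genome.chromosome_sequences[gene.chrom]
        cds = genome.coding_sequence(gene)
        if len(cds) % 3 != 0:
            raise ValueError(f"gene {gene.gene_id}: CDS not divisible by 3")
        for cds_pos in range(len(cds)):
            if gene.strand == "+":
                gpos = gene.start + cds_pos
            else:
                gpos = gene.end - 1 - cds_pos
            g_ref = seq[gpos]
            five, three = seq[gpos - 1], seq[gpos + 1]
            codon_i, offset = divmod(cds_pos, 3)
            ref_codon = cds[3 * codon_i : 3 * codon_i + 3]
            for cds_alt in BASES:
                if cds_alt == cds[cds_pos]:
                    continue
                alt_codon = ref_codon[:offset] + cds_alt + ref_codon[offset + 1 :]
                g_alt = cds_alt if gene.strand == "+" else complement(cds_alt)
                rows_chrom.append(gene.chrom)
                rows["pos"].append(gpos + 1)
                rows["ref"].append(g_ref)
                rows["alt"].append(g_alt)
                rows["gene_id"].append(gene.gene_id)
                rows["context"].append(context_index(g_ref, g_alt, five, three))
                rows["effect"].append(_classify(ref_codon, alt_codon))
    return pd.DataFrame({"chrom": rows_chrom, **rows})


def count_opportunities(
    genome: GenomeModel, changes: pd.DataFrame | None = None
) -> OpportunityTable:
    """Tabulate synonymous/missense/nonsense opportunities per 96-context."""
    if changes is None:
        changes = enumerate_coding_changes(genome)
    exome = np.zeros((96, 3), dtype=int)
    per_gene: dict[str, np.ndarray] = {}
    eff_col = changes["effect"].map(_EFFECT_COL).to_numpy()
    ctx = changes["context"].to_numpy()
    np.add.at(exome, (ctx, eff_col), 1)
    for gene_id, grp in changes.groupby("gene_id", sort=False):
        arr = np.zeros((96, 3), dtype=int)
        np.add.at(
            arr,
            (grp["context"].to_numpy(), grp["effect"].map(_EFFECT_COL).to_numpy()),
            1,
        )
        per_gene[gene_id] = arr
    return OpportunityTable(
        exome=exome, per_gene=per_gene, coding_bases=genome.total_coding_bases
    )


def draw_coding_snvs(
    genome: GenomeModel,
    n: int,
    seed: int,
    context_weights: np.ndarray | None = None,
    effect_weights: dict[str, float] | None = None,
    changes: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Sample ``n`` somatic SNVs over the exome's coding changes.

    With default weights, changes are drawn uniformly over all possible
    coding single-base substitutions — strict neutrality with a uniform
    mutation process.  ``context_weights`` (length 96) imposes a
    context-dependent mutational bias; ``effect_weights`` imposes selection
    (e.g. ``{"missense": 3.0}``).  Sampling is with replacement.
    """
    if changes is None:
        changes = enumerate_coding_changes(genome)
    w = np.ones(len(changes))
    if context_weights is not None:
        context_weights = np.asarray(context_weights, dtype=float)
        if context_weights.shape != (96,):
            raise ValueError("context_weights must have length 96")
        w *= context_weights[changes["context"].to_numpy()]
    if effect_weights:
        w *= changes["effect"].map(lambda e: effect_weights.get(e, 1.0)).to_numpy()
    rng = np.random.default_rng([seed, 0xD4D])
    idx = rng.choice(len(changes), size=n, replace=True, p=w / w.sum())
    return changes.iloc[idx].reset_index(drop=True)


def observations_from_variants(variants, genome: GenomeModel) -> pd.DataFrame:
    """Annotate somatic SNVs into the (context, effect, gene_id) frame.

    ``variants`` is an iterable of objects with chrom/pos/ref/alt (1-based).
    Intergenic variants are dropped: dN/dS concerns coding changes only.
    """
    rows = {k: [] for k in ("chrom", "pos", "ref", "alt", "gene_id", "context", "effect")}
    for v in variants:
        cons = annotate(v.chrom, v.pos, v.ref, v.alt, genome)
        if cons.element != "exonic":
            continue
        pos0 = v.pos - 1
        tri = genome.trinucleotide(v.chrom, pos0)
        rows["chrom"].append(v.chrom)
        rows["pos"].append(v.pos)
        rows["ref"].append(v.ref)
        rows["alt"].append(v.alt)
        rows["gene_id"].append(cons.gene_id)
        rows["context"].append(context_index(v.ref, v.alt, tri[0], tri[2]))
        rows["effect"].append(cons.coding_effect)
    return pd.DataFrame(rows)


def _rate_groups(
    syn_obs: np.ndarray, syn_opp: np.ndarray, min_obs: int
) -> tuple[np.ndarray, np.ndarray, int]:
    """Hierarchical pooling of the 96 classes into rate groups.

    A class with at least ``min_obs`` observed synonymous mutations keeps
    its own rate group; the sparse classes within each pyrimidine
    substitution type share one pooled group.  Returns (group_id[96],
    rates[96] from synonymous counts, number of pooled classes).
    """
    group_id = np.full(96, -1)
    rates = np.zeros(96)
    pooled = 0
    next_gid = 0
    global_rate = syn_obs.sum() / max(syn_opp.sum(), 1)
    for t in range(6):  # the 6 pyrimidine substitution types
        sl = slice(16 * t, 16 * (t + 1))
        obs_t, opp_t = syn_obs[sl], syn_opp[sl]
        rich = (obs_t >= min_obs) & (opp_t > 0)
        sparse = ~rich
        gids = np.full(16, -1)
        rates_t = np.zeros(16)
        for j in np.flatnonzero(rich):
            gids[j] = next_gid
            next_gid += 1
            rates_t[j] = obs_t[j] / opp_t[j]
        if sparse.any():
            sparse_opp = opp_t[sparse].sum()
            gids[sparse] = next_gid
            next_gid += 1
            rates_t[sparse] = (
                obs_t[sparse].sum() / sparse_opp if sparse_opp > 0 else global_rate
            )
            pooled += int(sparse.sum())
        group_id[sl] = gids
        rates[sl] = rates_t
    return group_id, rates, pooled


def _profile_loglik_machinery(
    group_id: np.ndarray,
    obs_by_class: np.ndarray,  # (96, 3) observed counts
    opp: np.ndarray,  # (96, 3) opportunities
):
    """Group-level sufficient statistics for the joint Poisson model.

    The model: synonymous counts in group g are Poisson(mu_g * Os_g) and
    nonsynonymous counts are Poisson(omega * mu_g * On_g); the nuisance
    rates mu_g are profiled out analytically, leaving a 1-parameter profile
    log-likelihood in omega.  This propagates the uncertainty of the
    synonymous-derived rates into the neutrality test and the CI.
    """
    n_groups = int(group_id.max()) + 1
    S_g = np.zeros(n_groups)
    N_g = np.zeros(n_groups)
    Os_g = np.zeros(n_groups)
    On_g = np.zeros(n_groups)
    for c in range(96):
        g = group_id[c]
        S_g[g] += obs_by_class[c, 0]
        N_g[g] += obs_by_class[c, 1] + obs_by_class[c, 2]
        Os_g[g] += opp[c, 0]
        On_g[g] += opp[c, 1] + opp[c, 2]
    keep = (Os_g + On_g) > 0
    S_g, N_g, Os_g, On_g = S_g[keep], N_g[keep], Os_g[keep], On_g[keep]

    def profile_loglik(omega: float) -> float:
        denom = Os_g + omega * On_g
        mu = np.where(denom > 0, (S_g + N_g) / denom, 0.0)
        lam_s = mu * Os_g
        lam_n = omega * mu * On_g
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = np.where(S_g > 0, S_g * np.log(np.maximum(lam_s, 1e-300)), 0.0)
            ll = ll + np.where(N_g > 0, N_g * np.log(np.maximum(lam_n, 1e-300)), 0.0)
        return float(ll.sum() - (lam_s + lam_n).sum())

    def mle() -> float:
        n_tot = N_g.sum()
        if n_tot == 0:
            return 0.0
        omega = 1.0
        for _ in range(200):
            mu = (S_g + N_g) / (Os_g + omega * On_g)
            new = n_tot / float(mu @ On_g)
            if abs(new - omega) < 1e-12:
                omega = new
                break
            omega = new
        return omega

    return profile_loglik, mle


def _poisson_lrt(n: int, expected: float) -> float:
    if expected <= 0:
        return 1.0
    if n == 0:
        dev = 2.0 * expected
    else:
        dev = 2.0 * (n * np.log(n / expected) - (n - expected))
    return float(stats.chi2.sf(dev, df=1))


def _profile_ci(n: int, expected: float, level: float = 0.95) -> tuple[float, float]:
    """Profile-likelihood CI for omega in N ~ Poisson(omega * expected)."""
    crit = stats.chi2.ppf(level, df=1)
    mle = n / expected

    def dev(omega: float) -> float:
        lam = omega * expected
        if n == 0:
            return 2.0 * lam - crit
        return 2.0 * (n * np.log(n / lam) - (n - lam)) - crit

    lo = 0.0
    if n > 0:
        lo = brentq(dev, 1e-12, mle)
    hi_bracket = max(mle, 1e-6) * 2
    while dev(hi_bracket) < 0:
        hi_bracket *= 2
    hi = brentq(dev, max(mle, 1e-12), hi_bracket)
    return (float(lo), float(hi))


def estimate_dnds(
    observations: pd.DataFrame,
    opportunities: OpportunityTable,
    min_obs: int = 5,
    per_gene: bool = True,
) -> tuple[DndsEstimate, list[DndsEstimate]]:
    """Exome-wide (and optionally per-gene) context-corrected dN/dS.

    ``observations`` is the frame from :func:`observations_from_variants`
    (recurrent variants already excluded upstream).  Context rates are
    estimated exome-wide from synonymous observations; per-gene estimates
    reuse those rates against gene-local opportunities, and are reported as
    undefined (None ratios) for genes with no observed substitutions.
    """
    obs_by_class = np.zeros((96, 3))
    counts = observations.groupby(["context", "effect"]).size()
    for (ctx, eff), n in counts.items():
        obs_by_class[ctx, _EFFECT_COL[eff]] += n
    if obs_by_class[:, 0].sum() == 0:
        raise ValueError(
            "no synonymous observations exome-wide: context rates inestimable"
        )
    syn_opp = opportunities.exome[:, 0].astype(float)
    group_id, rates, pooled = _rate_groups(obs_by_class[:, 0], syn_opp, min_obs)

    # exome scope: joint Poisson model, nuisance rates profiled out
    profile_ll, mle = _profile_loglik_machinery(
        group_id, obs_by_class, opportunities.exome.astype(float)
    )
    n_syn = int(obs_by_class[:, 0].sum())
    n_mis = int(obs_by_class[:, 1].sum())
    n_non = int(obs_by_class[:, 2].sum())
    e_mis = float(rates @ opportunities.exome[:, 1])
    e_non = float(rates @ opportunities.exome[:, 2])
    r_mis = n_mis / e_mis if e_mis > 0 else None
    r_non = n_non / e_non if e_non > 0 else None
    omega_hat = mle()
    ll_hat = profile_ll(omega_hat if omega_hat > 0 else 1e-12)
    dev = 2.0 * (ll_hat - profile_ll(1.0))
    p = float(stats.chi2.sf(max(dev, 0.0), df=1))
    crit = stats.chi2.ppf(0.95, df=1)

    def drop(omega: float) -> float:
        return 2.0 * (ll_hat - profile_ll(omega)) - crit

    if omega_hat > 0:
        lo = brentq(drop, 1e-9, omega_hat) if drop(1e-9) > 0 else 0.0
        hi_bracket = omega_hat * 2
        while drop(hi_bracket) < 0:
            hi_bracket *= 2
        hi = brentq(drop, omega_hat, hi_bracket)
        ci = (float(lo), float(hi))
    else:
        ci = (0.0, 0.0)
    exome_est = DndsEstimate(
        "exome-wide", n_syn, n_mis, n_non, r_mis, r_non, omega_hat, ci, p, pooled
    )

    # per-gene scopes: exome-wide synonymous rates treated as fixed (each
    # gene is a small fraction of the exome, so rate uncertainty is
    # negligible at this scale)
    gene_ests: list[DndsEstimate] = []
    if per_gene:
        for gene_id in sorted(opportunities.per_gene):
            obs_g = observations[observations["gene_id"] == gene_id]
            opp_g = opportunities.per_gene[gene_id].astype(float)
            gs = int((obs_g["effect"] == "synonymous").sum())
            gm = int((obs_g["effect"] == "missense").sum())
            gn = int((obs_g["effect"] == "nonsense").sum())
            if gs + gm + gn == 0:
                gene_ests.append(
                    DndsEstimate(gene_id, 0, 0, 0, None, None, None, None, None, pooled)
                )
                continue
            ge_mis = float(rates @ opp_g[:, 1])
            ge_non = float(rates @ opp_g[:, 2])
            ge_all = ge_mis + ge_non
            gn_all = gm + gn
            gene_ests.append(
                DndsEstimate(
                    gene_id, gs, gm, gn,
                    gm / ge_mis if ge_mis > 0 else None,
                    gn / ge_non if ge_non > 0 else None,
                    gn_all / ge_all if ge_all > 0 else None,
                    _profile_ci(gn_all, ge_all) if ge_all > 0 else None,
                    _poisson_lrt(gn_all, ge_all) if ge_all > 0 else None,
                    pooled,
                )
            )
    return exome_est, gene_ests


def naive_dnds(observations: pd.DataFrame, opportunities: OpportunityTable) -> float:
    """Uncorrected N/S count ratio normalized by the global opportunity ratio.

    Ignores context-specific rates; provided as the comparison baseline that
    the corrected estimator exists to improve on.
    """
    n_syn = int((observations["effect"] == "synonymous").sum())
    n_nonsyn = int(observations["effect"].isin(["missense", "nonsense"]).sum())
    if n_syn == 0:
        raise ValueError("no synonymous observations")
    opp_syn = opportunities.exome[:, 0].sum()
    opp_nonsyn = opportunities.exome[:, 1:].sum()
    return (n_nonsyn / opp_nonsyn) / (n_syn / opp_syn)


def dnds_table(exome: DndsEstimate, genes: list[DndsEstimate]) -> pd.DataFrame:
    rows = []
    for e in [exome, *genes]:
        rows.append(
            {
                "scope": e.scope,
                "n_syn": e.n_syn,
                "n_mis": e.n_mis,
                "n_non": e.n_non,
                "dnds_mis": e.ratio_mis,
                "dnds_trunc": e.ratio_trunc,
                "dnds_all": e.ratio_all,
                "ci_lo": e.ci_all[0] if e.ci_all else None,
                "ci_hi": e.ci_all[1] if e.ci_all else None,
                "p_value": e.p_value,
            }
        )
    return pd.DataFrame(rows)
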
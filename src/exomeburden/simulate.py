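"""Synthetic tumor-normal exome cohort generator.

Emulates the data structure of a small matched tumor/normal exome study of
metastatic kidney cancer: ~10 patients, a cohort somatic SNV load on the
order of 10^3, somatic spectra drawn from a mixture of mutational-signature
profiles, germline variants shared across patients through a common pool,
homopolymer indel artifacts typical of semiconductor sequencing chemistry,
caller quality flags, and a binary mortality label with planted per-gene
burden effects in deceased patients.

Every emitted call carries exactly one truth label (somatic, germline or
artifact) in the accompanying :class:`TruthRecord`, so each downstream
filtering and inference stage can be scored against ground truth.

Site partition: a fixed fraction of genome positions is reserved for
germline variation (pool and private) and the complement for somatic
variation, so a somatic allele can never collide with a germline allele of
another patient.  This makes panel-of-normals subtraction exact at toy
scale; real data offer no such guarantee.

Randomness: one pseudo-random stream per patient, derived from the master
seed with fixed offsets — adding a patient never perturbs earlier patients'
data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .contexts import (
    PYRIMIDINES,
    REF_TRINUCLEOTIDES,
    canonical_trinucleotide,
    complement,
    parse_label,
    CONTEXT_LABELS,
)
from .filtering import FLAG_VOCABULARY
from .genome import GenomeModel
from .signatures import SignatureCatalog

#: Fraction of usable genome positions reserved for germline variation.
GERMLINE_SITE_FRACTION = 0.3

_FLAGS = tuple(sorted(FLAG_VOCABULARY))


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the emulated study: 10 tumor-normal pairs, ~900 somatic
    SNVs per tumor (cohort load on the order of 10^3-10^4), 40% mortality,
    read support around 30x with a 5% low-support contamination fraction,
    and a 54% exonic placement of somatic variants.
    """

    n_patients: int = 10
    somatic_rate: float = 900.0
    germline_rate: float = 200.0
    shared_germline_fraction: float = 0.5
    signature_exposures: list[list[float]] | list[float] | None = None
    artifact_flag_rate: float = 0.02
    homopolymer_indel_rate: float = 50.0
    burden_effects: list[tuple[str, float]] = field(default_factory=list)
    mortality_fraction: float = 0.4
    read_support_mean: float = 30.0
    low_support_fraction: float = 0.05
    joint_flag_rate: float = 0.01
    exonic_fraction: float = 0.54
    germline_hom_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError(f"n_patients must be >= 1, got {self.n_patients}")
        for name in (
            "somatic_rate", "germline_rate", "artifact_flag_rate",
            "homopolymer_indel_rate", "read_support_mean",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in (
            "shared_germline_fraction", "mortality_fraction",
            "low_support_fraction", "joint_flag_rate", "exonic_fraction",
            "germline_hom_fraction",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for gene_id, mult in self.burden_effects:
            if mult < 0:
                raise ValueError(f"burden multiplier for {gene_id} must be >= 0")

    def exposures_for(self, patient_idx: int, n_signatures: int) -> np.ndarray:
        if self.signature_exposures is None:
            raise ValueError("signature_exposures not configured")
        exp = self.signature_exposures
        if exp and isinstance(exp[0], (list, tuple, np.ndarray)):
            vec = np.asarray(exp[patient_idx], dtype=float)
        else:
            vec = np.asarray(exp, dtype=float)
        if vec.shape != (n_signatures,):
            raise ValueError(
                f"exposure vector length {vec.shape} does not match catalog "
                f"({n_signatures} signatures)"
            )
        if np.any(vec < 0) or abs(vec.sum() - 1) > 1e-6:
            raise ValueError("exposure weights must be non-negative and sum to 1")
        return vec

    def to_yaml(self, path: str | Path) -> None:
        d = dict(self.__dict__)
        d["burden_effects"] = [list(t) for t in self.burden_effects]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "burden_effects" in d and d["burden_effects"]:
            d["burden_effects"] = [tuple(t) for t in d["burden_effects"]]
        return cls(**d)


@dataclass
class TruthRecord:
    """Ground truth for one simulated cohort."""

    # (patient, chrom, pos, ref, alt) -> 'somatic' | 'germline' | 'artifact'
    labels: dict[tuple[str, str, int, str, str], str]
    exposures: dict[str, np.ndarray]
    burden_multipliers: dict[str, float]
    vital_status: dict[str, str]

    def count(self, label: str) -> int:
        return sum(1 for v in self.labels.values() if v == label)

    def variants_of(self, patient: str, label: str) -> set[tuple[str, int, str, str]]:
        return {
            (c, p, r, a)
            for (pt, c, p, r, a), lab in self.labels.items()
            if pt == patient and lab == label
        }

    def write(self, tsv_path: str | Path, json_path: str | Path) -> None:
        import json

        with open(tsv_path, "w") as fh:
            fh.write("patient_id\tchrom\tpos\tref\talt\tlabel\n")
            for (pt, c, p, r, a), lab in sorted(self.labels.items()):
                fh.write(f"{pt}\t{c}\t{p}\t{r}\t{a}\t{lab}\n")
        with open(json_path, "w") as fh:
            json.dump(
                {
                    "exposures": {p: list(map(float, e)) for p, e in self.exposures.items()},
                    "burden_multipliers": self.burden_multipliers,
                    "vital_status": self.vital_status,
                },
                fh,
                indent=2,
            )


@dataclass(frozen=True)
class _Call:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    genotype: str  # 'het' | 'hom'
    read_support: int
    flags: tuple[str, ...]
    joint_flags: tuple[str, ...]


# ---------------------------------------------------------------------------
# site indexing
# ---------------------------------------------------------------------------


class _SiteIndex:
    """Positions of the genome bucketed by canonical trinucleotide class,
    exonic/intergenic zone and germline/somatic eligibility."""

    def __init__(self, genome: GenomeModel, seed: int):
        self.genome = genome
        rng = np.random.default_rng([seed, 0x51E5])
        chrom = sorted(genome.chromosome_sequences)[0]
        seq = genome.chromosome_sequences[chrom]
        self.chrom = chrom
        n = len(seq)
        # 1-based positions with both flanks defined: 2 .. n-1
        pos = np.arange(2, n)
        germline_eligible = rng.random(len(pos)) < GERMLINE_SITE_FRACTION
        gene_idx = np.full(len(pos), -1)
        gene_ids = [g.gene_id for g in genome.genes]
        for gi, g in enumerate(genome.genes):
            # gene covers 1-based positions start+1 .. end; array index = pos - 2
            gene_idx[g.start - 1 : g.end - 1] = gi
        self.gene_ids = gene_ids
        tri_class = np.array(
            [REF_TRINUCLEOTIDES.index(canonical_trinucleotide(seq[p - 2 : p + 1]))
             for p in pos]
        )
        self.germline_positions = pos[germline_eligible]
        # somatic buckets: class32 -> zone -> (positions, gene indices)
        self.somatic: dict[int, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
        som = ~germline_eligible
        for c in range(len(REF_TRINUCLEOTIDES)):
            mask = som & (tri_class == c)
            exonic = mask & (gene_idx >= 0)
            inter = mask & (gene_idx < 0)
            self.somatic[c] = {
                "exonic": (pos[exonic], gene_idx[exonic]),
                "intergenic": (pos[inter], gene_idx[inter]),
            }
        self.homopolymer_runs = _find_homopolymer_runs(seq)

    def base(self, pos1: int) -> str:
        """Reference base at a 1-based position."""
        return self.genome.chromosome_sequences[self.chrom][pos1 - 1]


def _find_homopolymer_runs(seq: str, min_len: int = 4) -> list[tuple[int, int]]:
    """(start0, length) of runs of >= min_len identical bases, off the edges."""
    runs = []
    i, n = 0, len(seq)
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= min_len and i > 1 and j < n - 1:
            runs.append((i, j - i))
        i = j
    return runs


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------


def _draw_read_support(rng, cfg: CohortConfig) -> int:
    if rng.random() < cfg.low_support_fraction:
        return int(rng.integers(1, 3))
    return 1 + int(rng.poisson(max(cfg.read_support_mean - 1, 0)))


def _draw_flags(rng, cfg: CohortConfig) -> tuple[str, ...]:
    return tuple(f for f in _FLAGS if rng.random() < cfg.artifact_flag_rate)


def simulate_cohort(
    genome: GenomeModel,
    config: CohortConfig,
    catalog: SignatureCatalog,
    outdir: str | Path,
) -> tuple[dict[tuple[str, str], Path], TruthRecord]:
    """Simulate and write one cohort: VCFs per sample plus the truth record.

    Returns a mapping (patient, tissue) -> VCF path and the
    :class:`TruthRecord`.  Deterministic given config.seed.
    """
    for gene_id, _ in config.burden_effects:
        genome.gene_by_id(gene_id)  # KeyError if the planted gene is missing
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    index = _SiteIndex(genome, config.seed)
    n = config.n_patients
    patients = [f"P{i + 1:02d}" for i in range(n)]

    # vital status: deterministic largest-remainder assignment, so any prefix
    # of n patients carries floor(n * mortality_fraction) deceased and adding
    # a patient never relabels an earlier one
    f = config.mortality_fraction
    vital = {
        patients[i]: (
            "deceased" if int((i + 1) * f) > int(i * f) else "alive"
        )
        for i in range(n)
    }

    # shared germline pool from its own stream (patient- and n-independent)
    pool_rng = np.random.default_rng([config.seed, 0xC0407])
    pool_size = max(1, int(round(config.germline_rate)))
    pool_pos = pool_rng.choice(
        index.germline_positions, size=min(pool_size, len(index.germline_positions)),
        replace=False,
    )
    pool = []
    for p in pool_pos:
        ref = index.base(int(p))
        alt = str(pool_rng.choice([b for b in "ACGT" if b != ref]))
        pool.append((index.chrom, int(p), ref, alt))

    multipliers = dict(config.burden_effects)
    gene_mult = np.ones(len(index.gene_ids))
    for gi, gid in enumerate(index.gene_ids):
        if gid in multipliers:
            gene_mult[gi] = multipliers[gid]

    labels: dict[tuple[str, str, int, str, str], str] = {}
    exposures_truth: dict[str, np.ndarray] = {}
    files: dict[tuple[str, str], Path] = {}
    pool_keys = {(c, p, r, a) for (c, p, r, a) in pool}

    for i, patient in enumerate(patients):
        rng = np.random.default_rng([config.seed, 0x9A71E47, i])
        exposures = config.exposures_for(i, catalog.n_signatures)
        exposures_truth[patient] = exposures
        category_probs = catalog.matrix @ exposures

        # ---- germline -----------------------------------------------------
        n_germ = rng.poisson(config.germline_rate)
        germline: dict[tuple[str, int, str, str], str] = {}
        attempts = 0
        while len(germline) < n_germ and attempts < 50 * max(n_germ, 1):
            attempts += 1
            if pool and rng.random() < config.shared_germline_fraction:
                key = pool[int(rng.integers(len(pool)))]
            else:
                p = int(rng.choice(index.germline_positions))
                ref = index.base(p)
                alt = str(rng.choice([b for b in "ACGT" if b != ref]))
                key = (index.chrom, p, ref, alt)
                if key in pool_keys:
                    continue
            if key not in germline:
                gt = "hom" if rng.random() < config.germline_hom_fraction else "het"
                germline[key] = gt

        # ---- somatic ------------------------------------------------------
        n_som = rng.poisson(config.somatic_rate)
        deceased = vital[patient] == "deceased"
        somatic: set[tuple[str, int, str, str]] = set()
        guard = 0
        while len(somatic) < n_som and guard < 50 * max(n_som, 1):
            guard += 1
            k = int(rng.choice(96, p=category_probs))
            ref_pyr, alt_pyr, five, three = parse_label(CONTEXT_LABELS[k])
            class32 = REF_TRINUCLEOTIDES.index(
                canonical_trinucleotide(five + ref_pyr + three)
            )
            zone = "exonic" if rng.random() < config.exonic_fraction else "intergenic"
            positions, gene_idx = index.somatic[class32][zone]
            if len(positions) == 0:
                continue
            if zone == "exonic" and deceased and (gene_mult != 1).any():
                w = gene_mult[gene_idx]
                j = int(rng.choice(len(positions), p=w / w.sum()))
            else:
                j = int(rng.integers(len(positions)))
            p = int(positions[j])
            g_ref = index.base(p)
            g_alt = alt_pyr if g_ref in PYRIMIDINES else complement(alt_pyr)
            somatic.add((index.chrom, p, g_ref, g_alt))

        # ---- artifacts: homopolymer indels per tissue ---------------------
        def draw_indels() -> set[tuple[str, int, str, str]]:
            out = set()
            if not index.homopolymer_runs:
                return out
            n_art = rng.poisson(config.homopolymer_indel_rate)
            for _ in range(n_art):
                start, length = index.homopolymer_runs[
                    int(rng.integers(len(index.homopolymer_runs)))
                ]
                anchor = index.base(start)      # 1-based anchor = run start
                run_base = index.base(start + 1)
                if rng.random() < 0.5:  # deletion of one run base
                    key = (index.chrom, start, anchor + run_base, anchor)
                else:  # insertion of one extra run base
                    key = (index.chrom, start, anchor, anchor + run_base)
                out.add(key)
            return out

        indels_tumor = draw_indels()
        indels_normal = draw_indels()

        # ---- assemble calls ----------------------------------------------
        joint_flag_of: dict[tuple[str, int, str, str], tuple[str, ...]] = {}
        for key in sorted(germline) + sorted(somatic):
            if rng.random() < config.joint_flag_rate:
                joint_flag_of[key] = (str(rng.choice(_FLAGS)),)

        def mk_call(key, genotype) -> _Call:
            chrom, pos, ref, alt = key
            return _Call(
                chrom=chrom, pos=pos, ref=ref, alt=alt, genotype=genotype,
                read_support=_draw_read_support(rng, config),
                flags=_draw_flags(rng, config),
                joint_flags=joint_flag_of.get(key, ()),
            )

        tumor_calls: dict[tuple, _Call] = {}
        normal_calls: dict[tuple, _Call] = {}
        for key, gt in sorted(germline.items()):
            tumor_calls[key] = mk_call(key, gt)
            normal_calls[key] = mk_call(key, gt)
            labels[(patient, *key)] = "germline"
        for key in sorted(somatic):
            if key in tumor_calls:
                continue
            tumor_calls[key] = mk_call(key, "het")
            labels[(patient, *key)] = "somatic"
        for key in sorted(indels_tumor):
            if key not in tumor_calls:
                tumor_calls[key] = mk_call(key, "het")
                labels[(patient, *key)] = "artifact"
        for key in sorted(indels_normal):
            if key not in normal_calls:
                normal_calls[key] = mk_call(key, "het")
                labels.setdefault((patient, *key), "artifact")

        for tissue, calls in (("tumor", tumor_calls), ("normal", normal_calls)):
            path = outdir / f"{patient}_{tissue}.vcf"
            _write_vcf(path, f"{patient}_{tissue}", calls, genome)
            files[(patient, tissue)] = path

    truth = TruthRecord(
        labels=labels,
        exposures=exposures_truth,
        burden_multipliers=multipliers,
        vital_status=vital,
    )
    return files, truth


# ---------------------------------------------------------------------------
# VCF output
# ---------------------------------------------------------------------------

_FILTER_DESCRIPTIONS = {
    "badReads": "Excess of reads with low quality around the variant",
    "MQ": "Low mapping quality",
    "strandBias": "Allele observed on predominantly one strand",
    "SC": "Low-complexity sequence context",
    "QD": "Low quality by depth",
}


def _write_vcf(
    path: Path, sample: str, calls: dict[tuple, _Call], genome: GenomeModel
) -> None:
    lines = ["##fileformat=VCFv4.2"]
    for flag in sorted(_FILTER_DESCRIPTIONS):
        lines.append(
            f'##FILTER=<ID={flag},Description="{_FILTER_DESCRIPTIONS[flag]}">'
        )
    lines.append(
        '##INFO=<ID=JF,Number=.,Type=String,'
        'Description="Quality flags re-acquired in the joint genotyping pass">'
    )
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        '##FORMAT=<ID=NR,Number=A,Type=Integer,'
        'Description="Reads supporting the alternate allele">'
    )
    for chrom in sorted(genome.chromosome_sequences):
        lines.append(
            f"##contig=<ID={chrom},length={len(genome.chromosome_sequences[chrom])}>"
        )
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample
    )
    gt_map = {"het": "0/1", "hom": "1/1"}
    for key in sorted(calls, key=lambda k: (k[0], k[1], k[2], k[3])):
        c = calls[key]
        filt = ";".join(sorted(c.flags)) if c.flags else "PASS"
        info = f"JF={','.join(c.joint_flags)}" if c.joint_flags else "."
        lines.append(
            f"{c.chrom}\t{c.pos}\t.\t{c.ref}\t{c.alt}\t100\t{filt}\t{info}\t"
            f"GT:NR\t{gt_map[c.genotype]}:{c.read_support}"
        )
    path.write_text("\n".join(lines) + "\n")
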
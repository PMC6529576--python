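"""Multi-stage refinement of raw tumor/normal variant calls to somatic SNVs.

The pipeline mirrors a conservative tumor-normal calling strategy for
amplicon exome data:

1. discard calls carrying any caller quality flag
   (``badReads``, ``MQ``, ``strandBias``, ``SC``, ``QD``);
2. merge all samples' calls, genotype every surviving locus across every
   sample, and discard variants that re-acquire a flag in the joint pass;
3. remove tumor calls whose allele appears in *any* patient's normal tissue
   (panel-of-normals germline subtraction);
4. remove calls supported by fewer than 3 reads;
5. restrict to single-nucleotide variants (indels are reported but excluded).

Variant identity is the exact (chromosome, position, ref, alt) tuple; no
allele normalization is attempted (a documented limitation for real data,
irrelevant for the simulator which emits normalized alleles).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path

import pysam

logger = logging.getLogger(__name__)

#: Caller quality flags that disqualify a call.
FLAG_VOCABULARY = frozenset({"badReads", "MQ", "strandBias", "SC", "QD"})

#: Minimum supporting reads for a somatic call.
MIN_READ_SUPPORT = 3

VariantKey = tuple[str, int, str, str]
SampleKey = tuple[str, str]  # (patient_id, tissue)
Cohort = dict[SampleKey, list["VariantCall"]]


@dataclass(frozen=True)
class VariantCall:
    """One called variant in one sample/tissue."""

    chrom: str
    pos: int  # 1-based (VCF convention)
    ref: str
    alt: str
    patient_id: str
    tissue: str  # 'tumor' | 'normal'
    read_support: int
    flags: frozenset[str] = frozenset()
    genotype: str = "het"  # het | hom | hom_ref | missing
    joint_flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.read_support < 0:
            raise ValueError("read_support must be >= 0")
        bad = self.flags - FLAG_VOCABULARY
        if bad:
            raise ValueError(
                f"unknown flags {sorted(bad)}; allowed: {sorted(FLAG_VOCABULARY)}"
            )
        if self.tissue not in ("tumor", "normal"):
            raise ValueError(f"tissue must be tumor/normal, got {self.tissue!r}")

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def is_present(self) -> bool:
        """True if the sample actually carries the alternate allele."""
        return self.genotype in ("het", "hom")


@dataclass(frozen=True)
class SomaticVariant:
    chrom: str
    pos: int
    ref: str
    alt: str
    read_support: int

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class SomaticSet:
    """Per-patient refined somatic SNVs with filter-funnel provenance."""

    patient_id: str
    variants: list[SomaticVariant]
    stage_counts: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.variants)

    @property
    def keys(self) -> set[VariantKey]:
        return {v.key for v in self.variants}


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------


def _split_sample_name(name: str, path: str) -> SampleKey:
    if "_" not in name:
        raise ValueError(
            f"{path}: sample name {name!r} does not encode patient and tissue "
            f"(expected '<patient>_<tumor|normal>')"
        )
    patient, tissue = name.rsplit("_", 1)
    if tissue not in ("tumor", "normal"):
        raise ValueError(
            f"{path}: sample name {name!r} has tissue {tissue!r}, "
            f"expected 'tumor' or 'normal'"
        )
    return patient, tissue


def _genotype_str(gt: tuple) -> str:
    if gt is None or all(a is None for a in gt):
        return "missing"
    alleles = [a for a in gt if a is not None]
    if all(a == 0 for a in alleles):
        return "hom_ref"
    if all(a > 0 for a in alleles):
        return "hom"
    return "het"


def parse_calls(paths: list[str | Path]) -> Cohort:
    """Parse per-sample VCF files into a cohort of :class:`VariantCall` lists.

    Each file must contain exactly one sample named ``<patient>_<tissue>``.
    Multi-allelic records are split into one call per alternate allele.
    Multiple files for the same sample (e.g., two caller parameterizations)
    are unioned, keeping the first occurrence of a duplicate allele key.
    """
    cohort: Cohort = {}
    seen_keys: dict[SampleKey, set[VariantKey]] = {}
    for path in paths:
        path = str(path)
        with pysam.VariantFile(path) as vcf:
            samples = list(vcf.header.samples)
            if len(samples) != 1:
                raise ValueError(
                    f"{path}: expected exactly one sample per file, found {samples}"
                )
            skey = _split_sample_name(samples[0], path)
            calls = cohort.setdefault(skey, [])
            keys = seen_keys.setdefault(skey, set())
            for rec_no, rec in enumerate(vcf.fetch() if vcf.index else vcf, start=1):
                try:
                    calls_from_rec = _record_to_calls(rec, skey)
                except ValueError as exc:
                    raise ValueError(f"{path}, record {rec_no}: {exc}") from None
                for call in calls_from_rec:
                    if call.key not in keys:
                        keys.add(call.key)
                        calls.append(call)
    return cohort


def _record_to_calls(rec, skey: SampleKey) -> list[VariantCall]:
    patient, tissue = skey
    filters = set(rec.filter.keys()) - {"PASS", "."}
    bad = filters - FLAG_VOCABULARY
    if bad:
        raise ValueError(
            f"unknown FILTER value(s) {sorted(bad)}; "
            f"allowed: {sorted(FLAG_VOCABULARY)} or PASS"
        )
    jf = rec.info.get("JF", ())
    if isinstance(jf, str):
        jf = (jf,)
    joint = frozenset(jf) & FLAG_VOCABULARY
    sample = rec.samples[0]
    gt = sample.get("GT")
    nr = sample.get("NR")
    if rec.alts is None:
        raise ValueError("record has no ALT allele")
    calls = []
    for i, alt in enumerate(rec.alts):
        if nr is None:
            support = 0
        elif isinstance(nr, (tuple, list)):
            support = int(nr[i]) if i < len(nr) and nr[i] is not None else 0
        else:
            support = int(nr)
        calls.append(
            VariantCall(
                chrom=rec.chrom,
                pos=rec.pos,
                ref=rec.ref,
                alt=alt,
                patient_id=patient,
                tissue=tissue,
                read_support=support,
                flags=frozenset(filters),
                genotype=_genotype_str(gt),
                joint_flags=joint,
            )
        )
    return calls


# ---------------------------------------------------------------------------
# filter stages
# ---------------------------------------------------------------------------


def filter_flagged(
    calls: list[VariantCall],
) -> tuple[list[VariantCall], dict[str, int]]:
    """Keep only calls with an empty flag set; report removals per flag.

    A call carrying several flags increments each flag's counter; the
    ``total_removed`` entry counts calls, not flags.
    """
    kept = []
    removed: Counter[str] = Counter()
    n_removed = 0
    for call in calls:
        if call.flags:
            n_removed += 1
            for f in call.flags:
                removed[f] += 1
        else:
            kept.append(call)
    counts = dict(removed)
    counts["total_removed"] = n_removed
    logger.info("flag filter: %d/%d calls removed (%s)", n_removed, len(calls), counts)
    return kept, counts


def merge_genotype_refilter(cohort: Cohort, original: Cohort | None = None) -> Cohort:
    """Union all samples' variant loci, genotype everywhere, drop joint-flagged.

    The merged variant set is the union of keys surviving the per-sample flag
    filter (``cohort``).  Every merged variant is then genotyped in every
    sample: if ``original`` (the pre-filter calls) is given, a sample's
    genotype is looked up there — re-genotyping recovers alleles whose
    per-sample call had been flag-discarded, which is what keeps a germline
    variant visible in its normal tissue when only the normal's call was
    flagged.  Samples with no call at all receive an imputed
    homozygous-reference entry with zero read support.  Variants that
    re-acquire a quality flag in the joint pass (non-empty ``joint_flags``
    in any sample) are removed from all samples.  The result is a
    rectangular variant x sample matrix.
    """
    if not cohort:
        raise ValueError("empty cohort")
    all_keys: dict[VariantKey, frozenset[str]] = {}
    for calls in cohort.values():
        for call in calls:
            all_keys[call.key] = all_keys.get(call.key, frozenset()) | call.joint_flags
    surviving = sorted(k for k, jf in all_keys.items() if not jf)
    n_joint = len(all_keys) - len(surviving)
    if n_joint:
        logger.info("joint re-filter: %d variant(s) removed", n_joint)
    out: Cohort = {}
    for skey, calls in cohort.items():
        patient, tissue = skey
        by_key = {c.key: c for c in calls}
        orig_by_key = (
            {c.key: c for c in original.get(skey, [])} if original is not None else {}
        )
        row = []
        for key in surviving:
            if key in by_key:
                row.append(by_key[key])
            elif key in orig_by_key:
                # re-genotyped from the pre-filter call; per-sample flags are
                # superseded by the joint evaluation
                row.append(replace(orig_by_key[key], flags=frozenset()))
            else:
                chrom, pos, ref, alt = key
                row.append(
                    VariantCall(
                        chrom=chrom,
                        pos=pos,
                        ref=ref,
                        alt=alt,
                        patient_id=patient,
                        tissue=tissue,
                        read_support=0,
                        genotype="hom_ref",
                    )
                )
        out[skey] = row
    return out


def classify_somatic(cohort: Cohort) -> dict[str, SomaticSet]:
    """Panel-of-normals germline subtraction, read-support and SNV filters.

    A tumor call is somatic iff its allele key is absent from every normal
    sample of every patient, it is supported by at least
    :data:`MIN_READ_SUPPORT` reads, and it is an SNV.  Stage removal counts
    are recorded per patient in :attr:`SomaticSet.stage_counts`.
    """
    normal_samples = [k for k in cohort if k[1] == "normal"]
    tumor_samples = [k for k in cohort if k[1] == "tumor"]
    if not normal_samples:
        raise ValueError(
            "cohort contains no normal samples: panel of normals undefined"
        )
    panel: set[VariantKey] = set()
    for skey in normal_samples:
        panel.update(c.key for c in cohort[skey] if c.is_present)
    out: dict[str, SomaticSet] = {}
    for skey in sorted(tumor_samples):
        patient = skey[0]
        present = [c for c in cohort[skey] if c.is_present]
        counts = {"tumor_calls": len(present)}
        stage = [c for c in present if c.key not in panel]
        counts["removed_in_normal"] = len(present) - len(stage)
        kept = [c for c in stage if c.read_support >= MIN_READ_SUPPORT]
        counts["removed_low_support"] = len(stage) - len(kept)
        snvs = [c for c in kept if c.is_snv]
        counts["removed_indel"] = len(kept) - len(snvs)
        counts["somatic_snvs"] = len(snvs)
        out[patient] = SomaticSet(
            patient_id=patient,
            variants=[
                SomaticVariant(c.chrom, c.pos, c.ref, c.alt, c.read_support)
                for c in sorted(snvs, key=lambda c: c.key)
            ],
            stage_counts=counts,
        )
    return out


def exclude_recurrent(
    somatic_sets: dict[str, SomaticSet], max_tumors: int = 1
) -> tuple[dict[str, SomaticSet], int]:
    """Remove variants recurring in more than ``max_tumors`` patients' tumors.

    Recurrent alleles in a small cohort are overwhelmingly residual germline
    leakage and would spuriously inflate selection estimates downstream.
    Returns the pruned sets and the number of distinct allele keys removed.
    """
    if max_tumors < 1:
        raise ValueError(f"max_tumors must be >= 1, got {max_tumors}")
    occurrence: Counter[VariantKey] = Counter()
    for ss in somatic_sets.values():
        occurrence.update(ss.keys)
    recurrent = {k for k, n in occurrence.items() if n > max_tumors}
    out = {}
    for patient, ss in somatic_sets.items():
        kept = [v for v in ss.variants if v.key not in recurrent]
        counts = dict(ss.stage_counts)
        counts["removed_recurrent"] = len(ss.variants) - len(kept)
        out[patient] = SomaticSet(patient_id=patient, variants=kept, stage_counts=counts)
    logger.info("recurrent-variant exclusion: %d allele key(s) removed", len(recurrent))
    return out, len(recurrent)


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------


def write_somatic_tsv(somatic_sets: dict[str, SomaticSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("patient_id\tchrom\tpos\tref\talt\tread_support\n")
        for patient in sorted(somatic_sets):
            for v in somatic_sets[patient].variants:
                fh.write(
                    f"{patient}\t{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{v.read_support}\n"
                )


def read_somatic_tsv(path: str | Path) -> dict[str, SomaticSet]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    out = {}
    for patient, grp in df.groupby("patient_id"):
        out[str(patient)] = SomaticSet(
            patient_id=str(patient),
            variants=[
                SomaticVariant(r.chrom, int(r.pos), r.ref, r.alt, int(r.read_support))
                for r in grp.itertuples()
            ],
        )
    return out


def funnel_report(somatic_sets: dict[str, SomaticSet]) -> dict:
    """Aggregate per-stage counts across patients (the filter funnel)."""
    totals: Counter[str] = Counter()
    for ss in somatic_sets.values():
        totals.update(ss.stage_counts)
    return {
        "per_patient": {p: ss.stage_counts for p, ss in sorted(somatic_sets.items())},
        "totals": dict(totals),
    }
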
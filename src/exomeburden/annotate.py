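"""Coding-consequence annotation of SNVs against the toy gene models.

Toy genes are pure coding sequence, so the element vocabulary collapses to
exonic/intergenic.  Coding SNVs are classified as synonymous, missense or
nonsense with the standard nuclear genetic code (NCBI table 1), strand-aware:
minus-strand genes translate the reverse complement.  Stop-loss changes are
binned as missense.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio.Seq import Seq

from .contexts import complement
from .genome import GenomeModel

ELEMENTS = ("exonic", "intergenic")
CODING_EFFECTS = ("synonymous", "missense", "nonsense", "not_applicable")


@dataclass(frozen=True)
class Consequence:
    element: str
    coding_effect: str
    gene_id: str | None = None
    codon_change: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if self.element not in ELEMENTS:
            raise ValueError(f"unknown element {self.element!r}")
        if self.coding_effect not in CODING_EFFECTS:
            raise ValueError(f"unknown coding_effect {self.coding_effect!r}")
        if (self.coding_effect == "not_applicable") != (self.element == "intergenic"):
            raise ValueError("coding_effect is not_applicable iff element is intergenic")


def _translate(codon: str) -> str:
    return str(Seq(codon).translate(table=1))


def annotate(
    chrom: str, pos: int, ref: str, alt: str, genome: GenomeModel
) -> Consequence:
    """Classify one SNV (1-based ``pos``) against the toy gene models."""
    if len(ref) != 1 or len(alt) != 1:
        raise ValueError(f"annotate handles SNVs only, got {ref}>{alt}")
    pos0 = pos - 1
    genome_ref = genome.base_at(chrom, pos0)  # raises if outside chromosome
    if genome_ref != ref:
        raise ValueError(
            f"reference mismatch at {chrom}:{pos}: expected {genome_ref}, got {ref}"
        )
    gene = genome.gene_at(chrom, pos0)
    if gene is None:
        return Consequence(element="intergenic", coding_effect="not_applicable")
    cds = genome.coding_sequence(gene)
    if gene.strand == "+":
        cds_pos = pos0 - gene.start
        cds_alt = alt
    else:
        cds_pos = gene.end - 1 - pos0
        cds_alt = complement(alt)
    codon_i, offset = divmod(cds_pos, 3)
    ref_codon = cds[3 * codon_i : 3 * codon_i + 3]
    alt_codon = ref_codon[:offset] + cds_alt + ref_codon[offset + 1 :]
    ref_aa = _translate(ref_codon)
    alt_aa = _translate(alt_codon)
    if alt_aa == ref_aa:
        effect = "synonymous"
    elif alt_aa == "*" and ref_aa != "*":
        effect = "nonsense"
    else:
        effect = "missense"  # includes stop-loss by design
    return Consequence(
        element="exonic",
        coding_effect=effect,
        gene_id=gene.gene_id,
        codon_change=(ref_codon, alt_codon),
    )


def annotate_many(
    variants, genome: GenomeModel, patient_ids=None
) -> pd.DataFrame:
    """Annotate an iterable of variants (objects with chrom/pos/ref/alt).

    Returns a tidy frame with one row per variant: chrom, pos, ref, alt,
    element, coding_effect, gene_id (and patient_id when supplied).
    """
    rows = []
    anonymous = patient_ids is None
    if anonymous:
        patient_ids = [None] * len(variants)
    for v, pid in zip(variants, patient_ids):
        c = annotate(v.chrom, v.pos, v.ref, v.alt, genome)
        rows.append(
            {
                "patient_id": pid,
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "element": c.element,
                "coding_effect": c.coding_effect,
                "gene_id": c.gene_id,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "patient_id", "chrom", "pos", "ref", "alt",
            "element", "coding_effect", "gene_id",
        ],
    )
    if anonymous:
        df = df.drop(columns=["patient_id"])
    return df


def consequence_summary(collections: dict[str, list[Consequence]]) -> pd.DataFrame:
    """Per-label proportions of element and coding-effect categories.

    Element proportions are over all variants of the label; coding-effect
    proportions are conditional on the variant being exonic (each block sums
    to 1).  Supports Fig.-1-style somatic-vs-germline comparisons.
    """
    rows = []
    for label, cons in collections.items():
        if not cons:
            raise ValueError(f"collection {label!r} is empty")
        n = len(cons)
        exonic = [c for c in cons if c.element == "exonic"]
        row = {
            "label": label,
            "n": n,
            "exonic": len(exonic) / n,
            "intergenic": 1 - len(exonic) / n,
        }
        ne = len(exonic)
        for eff in ("synonymous", "missense", "nonsense"):
            row[eff] = (
                sum(c.coding_effect == eff for c in exonic) / ne if ne else float("nan")
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("label")
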
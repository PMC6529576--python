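import textwrap

import pytest

from exomeburden.filtering import (
    SomaticSet,
    SomaticVariant,
    VariantCall,
    classify_somatic,
    exclude_recurrent,
    filter_flagged,
    funnel_report,
    merge_genotype_refilter,
    parse_calls,
    read_somatic_tsv,
    write_somatic_tsv,
)
from exomeburden.signatures import synthetic_catalog
from exomeburden.simulate import CohortConfig, simulate_cohort

VCF_HEADER = textwrap.dedent(
    """\
    ##fileformat=VCFv4.2
    ##FILTER=<ID=MQ,Description="x">
    ##FILTER=<ID=QD,Description="x">
    ##FILTER=<ID=SC,Description="x">
    ##FILTER=<ID=badReads,Description="x">
    ##FILTER=<ID=strandBias,Description="x">
    ##INFO=<ID=JF,Number=.,Type=String,Description="x">
    ##FORMAT=<ID=GT,Number=1,Type=String,Description="x">
    ##FORMAT=<ID=NR,Number=A,Type=Integer,Description="x">
    ##contig=<ID=chr1,length=1000>
    #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
    """
)


def write_vcf(path, sample, records):
    path.write_text(VCF_HEADER.format(sample=sample) + "".join(r + "\n" for r in records))
    return path


def call(chrom="chr1", pos=10, ref="A", alt="C", patient="P1", tissue="tumor",
         rs=10, flags=(), genotype="het", joint=()):
    return VariantCall(
        chrom=chrom, pos=pos, ref=ref, alt=alt, patient_id=patient, tissue=tissue,
        read_support=rs, flags=frozenset(flags), genotype=genotype,
        joint_flags=frozenset(joint),
    )


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------


def test_parse_pass_records_have_empty_flags(tmp_path):
    p = write_vcf(
        tmp_path / "P1_tumor.vcf", "P1_tumor",
        [
            "chr1\t10\t.\tA\tC\t100\tPASS\t.\tGT:NR\t0/1:12",
            "chr1\t20\t.\tG\tT\t100\tPASS\t.\tGT:NR\t0/1:9",
            "chr1\t30\t.\tC\tA\t100\tPASS\t.\tGT:NR\t1/1:30",
        ],
    )
    cohort = parse_calls([p])
    calls = cohort[("P1", "tumor")]
    assert len(calls) == 3
    assert all(c.flags == frozenset() for c in calls)
    assert calls[0].read_support == 12
    assert calls[2].genotype == "hom"


def test_parse_multiple_filter_values(tmp_path):
    p = write_vcf(
        tmp_path / "P1_tumor.vcf", "P1_tumor",
        ["chr1\t10\t.\tA\tC\t100\tstrandBias;MQ\t.\tGT:NR\t0/1:12"],
    )
    (c,) = parse_calls([p])[("P1", "tumor")]
    assert c.flags == frozenset({"strandBias", "MQ"})


def test_parse_multiallelic_split(tmp_path):
    """A 5-record toy file with one multi-allelic record yields 6 calls."""
    p = write_vcf(
        tmp_path / "P1_tumor.vcf", "P1_tumor",
        [
            "chr1\t10\t.\tA\tC,T\t100\tPASS\t.\tGT:NR\t0/1:12,7",
            "chr1\t20\t.\tG\tT\t100\tPASS\t.\tGT:NR\t0/1:9",
            "chr1\t30\t.\tC\tA\t100\tPASS\t.\tGT:NR\t0/1:8",
            "chr1\t40\t.\tT\tG\t100\tPASS\t.\tGT:NR\t0/1:22",
            "chr1\t50\t.\tA\tG\t100\tPASS\t.\tGT:NR\t0/1:5",
        ],
    )
    calls = parse_calls([p])[("P1", "tumor")]
    assert len(calls) == 6
    split = [c for c in calls if c.pos == 10]
    assert {(c.ref, c.alt) for c in split} == {("A", "C"), ("A", "T")}
    assert {c.read_support for c in split} == {12, 7}


def test_parse_unknown_filter_rejected(tmp_path):
    p = write_vcf(
        tmp_path / "P1_tumor.vcf", "P1_tumor",
        ["chr1\t10\t.\tA\tC\t100\tPASS\t.\tGT:NR\t0/1:12"],
    )
    text = p.read_text().replace("PASS", "weird").replace(
        "##FILTER=<ID=MQ", '##FILTER=<ID=weird,Description="x">\n##FILTER=<ID=MQ'
    )
    p.write_text(text)
    with pytest.raises(ValueError, match="allowed"):
        parse_calls([p])


def test_parse_bad_sample_name_rejected(tmp_path):
    p = write_vcf(
        tmp_path / "x.vcf", "sampleonly",
        ["chr1\t10\t.\tA\tC\t100\tPASS\t.\tGT:NR\t0/1:12"],
    )
    with pytest.raises(ValueError, match="patient and tissue"):
        parse_calls([p])


def test_parse_joint_flag_info(tmp_path):
    p = write_vcf(
        tmp_path / "P1_tumor.vcf", "P1_tumor",
        ["chr1\t10\t.\tA\tC\t100\tPASS\tJF=MQ\tGT:NR\t0/1:12"],
    )
    (c,) = parse_calls([p])[("P1", "tumor")]
    assert c.joint_flags == frozenset({"MQ"})


# ---------------------------------------------------------------------------
# flag filter
# ---------------------------------------------------------------------------


def test_filter_flagged_counts_and_order():
    calls = [call(pos=i, flags=(["MQ"] if i % 3 == 0 else [])) for i in range(10)]
    kept, counts = filter_flagged(calls)
    assert len(kept) == 6
    assert counts["total_removed"] == 4
    assert counts["MQ"] == 4
    assert [c.pos for c in kept] == sorted(c.pos for c in kept)  # order preserved


def test_filter_flagged_all_flagged_empty():
    calls = [call(pos=i, flags=["QD"]) for i in range(5)]
    kept, counts = filter_flagged(calls)
    assert kept == []
    assert counts["total_removed"] == 5


def test_filter_flagged_matches_hand_enumeration():
    flags_per_call = [
        (), ("MQ",), (), ("SC", "QD"), (), (), ("badReads",), (), (), ("strandBias",),
        (), (), ("MQ", "strandBias"), (), (), (), ("QD",), (), (), (),
    ]
    calls = [call(pos=i, flags=f) for i, f in enumerate(flags_per_call)]
    kept, _ = filter_flagged(calls)
    expected = [i for i, f in enumerate(flags_per_call) if not f]
    assert [c.pos for c in kept] == expected


def test_unknown_flag_rejected_at_construction():
    with pytest.raises(ValueError, match="unknown flags"):
        call(flags=["nope"])


# ---------------------------------------------------------------------------
# merge / joint re-filter
# ---------------------------------------------------------------------------


def test_merge_unions_and_imputes_hom_ref():
    cohort = {
        ("A", "tumor"): [call(patient="A", pos=10)],
        ("A", "normal"): [call(patient="A", tissue="normal", pos=20)],
        ("B", "tumor"): [call(patient="B", pos=20)],
    }
    merged = merge_genotype_refilter(cohort)
    # rectangular: every sample has both loci
    for skey, row in merged.items():
        assert {c.pos for c in row} == {10, 20}
    imputed = [c for c in merged[("B", "tumor")] if c.pos == 10][0]
    assert imputed.genotype == "hom_ref" and imputed.read_support == 0


def test_merge_joint_flagged_removed_everywhere():
    cohort = {
        ("A", "tumor"): [call(patient="A", pos=10, joint=("MQ",)), call(patient="A", pos=20)],
        ("B", "tumor"): [call(patient="B", pos=10)],
    }
    merged = merge_genotype_refilter(cohort)
    for row in merged.values():
        assert all(c.pos != 10 for c in row)


def test_merge_single_sample_equals_flag_filter():
    calls = [call(pos=10), call(pos=20, flags=["MQ"]), call(pos=30)]
    kept, _ = filter_flagged(calls)
    merged = merge_genotype_refilter({("P1", "tumor"): kept})
    assert merged[("P1", "tumor")] == kept


def test_merge_regenotypes_from_original_calls():
    """A flag-discarded normal call reappears via joint genotyping."""
    germ_t = call(patient="A", pos=10)
    germ_n = call(patient="A", tissue="normal", pos=10, flags=["MQ"], rs=15)
    original = {("A", "tumor"): [germ_t], ("A", "normal"): [germ_n]}
    filtered = {k: filter_flagged(v)[0] for k, v in original.items()}
    merged = merge_genotype_refilter(filtered, original=original)
    (n_call,) = merged[("A", "normal")]
    assert n_call.is_present and n_call.read_support == 15
    assert n_call.flags == frozenset()


# ---------------------------------------------------------------------------
# somatic classification
# ---------------------------------------------------------------------------


def make_cohort(tumor_calls, normal_calls):
    return {
        ("A", "tumor"): tumor_calls,
        ("A", "normal"): normal_calls,
    }


def test_variant_in_any_normal_removed_as_germline():
    # variant in patient B's normal removes it from patient A's tumor
    cohort = {
        ("A", "tumor"): [call(patient="A", pos=10)],
        ("A", "normal"): [],
        ("B", "tumor"): [],
        ("B", "normal"): [call(patient="B", tissue="normal", pos=10)],
    }
    sets = classify_somatic(cohort)
    assert len(sets["A"]) == 0
    assert sets["A"].stage_counts["removed_in_normal"] == 1


def test_low_support_removed_and_clean_retained():
    cohort = make_cohort(
        [call(pos=10, rs=2), call(pos=20, rs=10), call(pos=30, rs=3)],
        [],
    )
    sets = classify_somatic(cohort)
    assert {v.pos for v in sets["A"].variants} == {20, 30}
    assert sets["A"].stage_counts["removed_low_support"] == 1


def test_indels_excluded_from_somatic_set():
    cohort = make_cohort(
        [call(pos=10), call(pos=20, ref="A", alt="AT"), call(pos=30, ref="GC", alt="G")],
        [],
    )
    sets = classify_somatic(cohort)
    assert {v.pos for v in sets["A"].variants} == {10}
    assert sets["A"].stage_counts["removed_indel"] == 2


def test_hom_ref_and_missing_genotypes_not_counted_as_calls():
    cohort = make_cohort(
        [call(pos=10), call(pos=20, genotype="hom_ref"), call(pos=30, genotype="missing")],
        [call(pos=40, tissue="normal", genotype="hom_ref")],  # not a normal variant
    )
    sets = classify_somatic(cohort)
    assert {v.pos for v in sets["A"].variants} == {10}
    assert sets["A"].stage_counts["tumor_calls"] == 1


def test_no_normal_samples_is_an_error():
    with pytest.raises(ValueError, match="panel of normals"):
        classify_somatic({("A", "tumor"): [call(pos=10)]})


def test_classify_is_idempotent():
    cohort = make_cohort(
        [call(pos=10), call(pos=20, rs=2), call(pos=30, ref="A", alt="AT")],
        [call(pos=40, tissue="normal")],
    )
    first = classify_somatic(cohort)
    cohort2 = {
        ("A", "tumor"): [
            call(pos=v.pos, ref=v.ref, alt=v.alt, rs=v.read_support)
            for v in first["A"].variants
        ],
        ("A", "normal"): cohort[("A", "normal")],
    }
    second = classify_somatic(cohort2)
    assert second["A"].keys == first["A"].keys


def test_stage_counters_sum_to_input():
    cohort = make_cohort(
        [call(pos=p, rs=rs) for p, rs in [(10, 10), (20, 2), (30, 1), (40, 8)]]
        + [call(pos=50, ref="A", alt="AT")],
        [call(pos=40, tissue="normal")],
    )
    sc = classify_somatic(cohort)["A"].stage_counts
    assert (
        sc["tumor_calls"]
        == sc["removed_in_normal"]
        + sc["removed_low_support"]
        + sc["removed_indel"]
        + sc["somatic_snvs"]
    )


# ---------------------------------------------------------------------------
# recurrent exclusion
# ---------------------------------------------------------------------------


def somatic_set(patient, positions):
    return SomaticSet(
        patient_id=patient,
        variants=[SomaticVariant("chr1", p, "A", "C", 10) for p in positions],
    )


def test_recurrent_in_two_tumors_removed_from_both():
    sets = {"A": somatic_set("A", [10, 20]), "B": somatic_set("B", [10, 30])}
    out, n = exclude_recurrent(sets, max_tumors=1)
    assert n == 1
    assert {v.pos for v in out["A"].variants} == {20}
    assert {v.pos for v in out["B"].variants} == {30}


def test_private_variant_retained():
    sets = {"A": somatic_set("A", [10])}
    out, n = exclude_recurrent(sets)
    assert n == 0 and {v.pos for v in out["A"].variants} == {10}


def test_all_shared_yields_empty_sets():
    sets = {p: somatic_set(p, [10, 20]) for p in "ABC"}
    out, n = exclude_recurrent(sets)
    assert n == 2
    assert all(len(s) == 0 for s in out.values())


def test_max_tumors_two_keeps_pairs():
    sets = {"A": somatic_set("A", [10]), "B": somatic_set("B", [10]),
            "C": somatic_set("C", [20])}
    out, n = exclude_recurrent(sets, max_tumors=2)
    assert n == 0
    assert {v.pos for v in out["A"].variants} == {10}


# ---------------------------------------------------------------------------
# end-to-end soundness on simulated truth
# ---------------------------------------------------------------------------


def test_panel_soundness_and_sensitivity_on_truth(small_exome, tmp_path):
    """No germline leaks; every clean truth-somatic SNV survives."""
    from tests.conftest import refine_to_somatic

    catalog = synthetic_catalog(5, seed=1)
    cfg = CohortConfig(
        n_patients=5, somatic_rate=150, germline_rate=60,
        signature_exposures=[0.3, 0.3, 0.4, 0.0, 0.0],
        artifact_flag_rate=0.03, homopolymer_indel_rate=10,
        joint_flag_rate=0.01, seed=17,
    )
    files, truth = simulate_cohort(small_exome, cfg, catalog, tmp_path)
    # raw parse kept for flag/support lookup below
    cohort = parse_calls(sorted(str(p) for p in files.values()))
    sets = refine_to_somatic(files.values())
    for patient, ss in sets.items():
        germ = truth.variants_of(patient, "germline")
        assert not ss.keys & germ  # panel-of-normals soundness
        # sensitivity: clean truth somatic (unflagged, support >= 3) all survive
        tumor_calls = {c.key: c for c in cohort[(patient, "tumor")]}
        clean = {
            k for k in truth.variants_of(patient, "somatic")
            if not tumor_calls[k].flags
            and not tumor_calls[k].joint_flags
            and tumor_calls[k].read_support >= 3
        }
        assert clean <= ss.keys


def test_somatic_tsv_roundtrip(tmp_path):
    sets = {"A": somatic_set("A", [10, 20]), "B": somatic_set("B", [15])}
    write_somatic_tsv(sets, tmp_path / "s.tsv")
    back = read_somatic_tsv(tmp_path / "s.tsv")
    assert {p: s.keys for p, s in back.items()} == {p: s.keys for p, s in sets.items()}


def test_funnel_report_totals():
    sets = classify_somatic(
        make_cohort([call(pos=10), call(pos=20, rs=1)], [call(pos=30, tissue="normal")])
    )
    rep = funnel_report(sets)
    assert rep["totals"]["tumor_calls"] == 2
    assert rep["totals"]["somatic_snvs"] == 1
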
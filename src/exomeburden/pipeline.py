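"""End-to-end orchestration: simulate -> filter -> annotate -> burden ->
dN/dS -> signatures -> enrichment -> external validation.

A :class:`RunConfig` (YAML) names the inputs, toggles stages and carries all
stage parameters.  :func:`run_pipeline` executes the enabled stages in
dependency order, writes every artifact under the output directory and
returns a machine-readable :class:`RunReport` (JSON) holding the filter
funnel, the inflation factor, the dN/dS summary, selected signatures, top
enrichment terms and a config hash for provenance.  Re-running an identical
config reproduces identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotate import Consequence, annotate_many, consequence_summary
from .burden import burden_test, external_burden_test, inflation_lambda, rank_genes
from .dnds import (
    count_opportunities,
    dnds_table,
    estimate_dnds,
    observations_from_variants,
)
from .enrichment import load_gmt, subsample_sensitivity, enrich
from .filtering import (
    classify_somatic,
    exclude_recurrent,
    filter_flagged,
    funnel_report,
    merge_genotype_refilter,
    parse_calls,
    write_somatic_tsv,
)
from .genome import GenomeModel, build_toy_exome
from .signatures import (
    SignatureCatalog,
    select_and_refit,
    spectra_per_tumor,
    synthetic_catalog,
)
from .simulate import CohortConfig, simulate_cohort

logger = logging.getLogger(__name__)

STAGES = (
    "simulate", "filter", "annotate", "burden",
    "dnds", "signatures", "enrich", "validate_external",
)

#: Stage -> stages it depends on.
_DEPENDENCIES = {
    "filter": ["simulate"],
    "annotate": ["filter"],
    "burden": ["annotate"],
    "dnds": ["annotate"],
    "signatures": ["filter"],
    "enrich": ["burden"],
    "validate_external": ["burden"],
}


@dataclass
class RunConfig:
    outdir: str = "run"
    seed: int = 0
    stages: dict[str, bool] = field(
        default_factory=lambda: {s: s != "validate_external" for s in STAGES}
    )
    genome: dict = field(
        default_factory=lambda: {"n_genes": 100, "mean_cds_length": 900}
    )
    cohort: dict = field(default_factory=dict)
    catalog: str = "synthetic"
    gmt: str | None = None
    universe: str | None = None
    external_counts: dict | None = None
    burden_alpha: float = 0.05
    signature_threshold: float = 0.05
    n_bootstrap: int = 200
    subsampling: dict = field(
        default_factory=lambda: {
            "n_subsamples": 200, "size_min": 5, "size_max": 20, "alpha": 0.05,
        }
    )

    def enabled(self, stage: str) -> bool:
        return bool(self.stages.get(stage, False))

    def to_dict(self) -> dict:
        return {
            "outdir": self.outdir,
            "seed": self.seed,
            "stages": dict(self.stages),
            "genome": dict(self.genome),
            "cohort": dict(self.cohort),
            "catalog": self.catalog,
            "gmt": self.gmt,
            "universe": self.universe,
            "external_counts": self.external_counts,
            "burden_alpha": self.burden_alpha,
            "signature_threshold": self.signature_threshold,
            "n_bootstrap": self.n_bootstrap,
            "subsampling": dict(self.subsampling),
        }

    def hash(self) -> str:
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls(**d)


def validate_config(config: RunConfig) -> list[str]:
    """Return a list of problems; empty iff the pipeline can run."""
    problems = []
    unknown = set(config.stages) - set(STAGES)
    if unknown:
        problems.append(f"unknown stage toggle(s): {sorted(unknown)}")
    for stage, deps in _DEPENDENCIES.items():
        if config.enabled(stage):
            for dep in deps:
                if not config.enabled(dep):
                    problems.append(
                        f"stage '{stage}' is enabled but its dependency '{dep}' is not"
                    )
    if config.enabled("simulate"):
        g = config.genome
        if "fasta" in g or "genes" in g:
            for key in ("fasta", "genes"):
                if key not in g:
                    problems.append(f"genome.{key} missing (both needed to load a genome)")
                elif not Path(g[key]).exists():
                    problems.append(f"genome.{key}: path does not exist: {g[key]}")
        else:
            if g.get("n_genes", 0) < 1:
                problems.append("genome.n_genes must be >= 1")
    if config.enabled("signatures") or config.enabled("simulate"):
        if config.catalog != "synthetic" and not Path(config.catalog).exists():
            problems.append(f"catalog: path does not exist: {config.catalog}")
    if config.enabled("enrich"):
        if not config.gmt:
            problems.append("gmt: no gene-set library path configured")
        elif not Path(config.gmt).exists():
            problems.append(f"gmt: path does not exist: {config.gmt}")
    if config.enabled("validate_external"):
        ec = config.external_counts or {}
        for key in ("table", "total_deceased", "total_alive"):
            if key not in ec:
                problems.append(f"external_counts.{key} missing")
        if "table" in ec and not Path(ec["table"]).exists():
            problems.append(f"external_counts.table: path does not exist: {ec['table']}")
    try:
        CohortConfig(**{**config.cohort, "seed": config.seed})
    except (TypeError, ValueError) as exc:
        problems.append(f"cohort config invalid: {exc}")
    return problems


@dataclass
class RunReport:
    data: dict

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.data, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunReport":
        return cls(data=json.loads(Path(path).read_text()))

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.data, sort_keys=True).encode()
        ).hexdigest()[:16]


def _load_genome(config: RunConfig) -> GenomeModel:
    g = config.genome
    if "fasta" in g:
        return GenomeModel.read(g["fasta"], g["genes"])
    return build_toy_exome(
        n_genes=int(g.get("n_genes", 100)),
        mean_cds_length=int(g.get("mean_cds_length", 900)),
        seed=int(g.get("seed", config.seed)),
    )


def _load_catalog(config: RunConfig) -> SignatureCatalog:
    if config.catalog == "synthetic":
        return synthetic_catalog()
    return SignatureCatalog.from_tsv(config.catalog)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the enabled stages; write artifacts; return the run report."""
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid configuration:\n" + "\n".join(problems))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "config_hash": config.hash(),
        "seed": config.seed,
        "stages_run": [],
    }
    if not any(config.enabled(s) for s in STAGES):
        rep = RunReport(report)
        rep.to_json(outdir / "run_report.json")
        return rep

    genome = _load_genome(config)
    catalog = _load_catalog(config)
    genome.write(outdir / "genome.fasta", outdir / "genes.tsv")

    truth = None
    somatic_sets = None
    assignments = None
    ranked = None

    if config.enabled("simulate"):
        cohort_cfg = CohortConfig(**{**config.cohort, "seed": config.seed})
        if cohort_cfg.signature_exposures is None:
            cohort_cfg.signature_exposures = _default_exposures(catalog)
        files, truth = simulate_cohort(genome, cohort_cfg, catalog, outdir / "calls")
        truth.write(outdir / "truth_labels.tsv", outdir / "truth.json")
        cohort_cfg.to_yaml(outdir / "cohort_config.yaml")
        report["stages_run"].append("simulate")
        report["simulate"] = {
            "n_patients": cohort_cfg.n_patients,
            "n_calls_labeled": len(truth.labels),
            "n_somatic_truth": truth.count("somatic"),
            "n_germline_truth": truth.count("germline"),
            "n_artifact_truth": truth.count("artifact"),
        }

    if config.enabled("filter"):
        paths = sorted((outdir / "calls").glob("*.vcf"))
        cohort = parse_calls(paths)
        n_raw = sum(len(v) for v in cohort.values())
        flagged = {}
        for skey, calls in cohort.items():
            kept, _counts = filter_flagged(calls)
            flagged[skey] = kept
        merged = merge_genotype_refilter(flagged, original=cohort)
        somatic_sets = classify_somatic(merged)
        somatic_sets, n_recurrent = exclude_recurrent(somatic_sets)
        write_somatic_tsv(somatic_sets, outdir / "somatic.tsv")
        funnel = funnel_report(somatic_sets)
        funnel["raw_calls"] = n_raw
        funnel["recurrent_keys_removed"] = n_recurrent
        (outdir / "filter_funnel.json").write_text(json.dumps(funnel, indent=2))
        report["stages_run"].append("filter")
        report["filter"] = {
            "raw_calls": n_raw,
            "somatic_snvs": sum(len(s) for s in somatic_sets.values()),
            "recurrent_keys_removed": n_recurrent,
            "funnel_totals": funnel["totals"],
        }

    if config.enabled("annotate"):
        variants, patients = [], []
        for patient, ss in sorted(somatic_sets.items()):
            variants.extend(ss.variants)
            patients.extend([patient] * len(ss.variants))
        assignments = annotate_many(variants, genome, patient_ids=patients)
        assignments.to_csv(outdir / "annotated_somatic.tsv", sep="\t", index=False)
        cons = [
            Consequence(
                element=r.element,
                coding_effect=r.coding_effect,
                gene_id=r.gene_id if isinstance(r.gene_id, str) else None,
            )
            for r in assignments.itertuples()
        ]
        summary = consequence_summary({"somatic": cons}) if cons else None
        if summary is not None:
            summary.to_csv(outdir / "consequence_summary.tsv", sep="\t")
        report["stages_run"].append("annotate")
        report["annotate"] = {
            "n_variants": len(assignments),
            "n_exonic": int((assignments["element"] == "exonic").sum()),
        }

    vital = truth.vital_status if truth else _load_labels(config)

    if config.enabled("burden"):
        results = burden_test(assignments, vital)
        ranked = rank_genes(results, alpha=config.burden_alpha)
        ranked.to_csv(outdir / "burden_ranked.tsv", sep="\t", index=False)
        infl = inflation_lambda(ranked["p_value"])
        pd.DataFrame(
            {
                "expected": infl.expected_quantiles,
                "observed": infl.observed_quantiles,
            }
        ).to_csv(outdir / "qq.tsv", sep="\t", index=False)
        prioritized = ranked[ranked["prioritized"]]["gene_id"].tolist()
        report["stages_run"].append("burden")
        report["burden"] = {
            "n_genes_tested": len(ranked),
            "n_prioritized": len(prioritized),
            "prioritized_genes": prioritized,
            "lambda": infl.lam,
            "min_p": float(ranked["p_value"].min()),
        }

    if config.enabled("dnds"):
        variants = [v for ss in somatic_sets.values() for v in ss.variants]
        obs = observations_from_variants(variants, genome)
        opp = count_opportunities(genome)
        exome_est, gene_ests = estimate_dnds(obs, opp)
        dnds_table(exome_est, gene_ests).to_csv(
            outdir / "dnds.tsv", sep="\t", index=False
        )
        report["stages_run"].append("dnds")
        report["dnds"] = {
            "exome_ratio": exome_est.ratio_all,
            "exome_ci": list(exome_est.ci_all) if exome_est.ci_all else None,
            "neutrality_p": exome_est.p_value,
            "n_syn": exome_est.n_syn,
            "n_mis": exome_est.n_mis,
            "n_non": exome_est.n_non,
        }

    if config.enabled("signatures"):
        spectra = spectra_per_tumor(somatic_sets, genome)
        spectra.to_csv(outdir / "spectra.tsv", sep="\t")
        exposure_rows = []
        selected_union: set[str] = set()
        # cohort-level selection from the pooled spectrum: per-tumor spectra
        # at a few hundred SNVs are too noisy for a stable active set
        pooled = spectra.sum(axis=1).to_numpy()
        cohort_selected: list[str] = []
        if pooled.sum() >= 1:
            pooled_est = select_and_refit(
                pooled, catalog,
                threshold=config.signature_threshold,
                n_bootstrap=config.n_bootstrap,
                seed=config.seed,
            )
            cohort_selected = [
                n for n, sel in zip(pooled_est.signatures, pooled_est.selected) if sel
            ]
            df = pooled_est.as_frame()
            df.insert(0, "patient_id", "cohort")
            exposure_rows.append(df)
        for patient in spectra.columns:
            spec = spectra[patient].to_numpy()
            if spec.sum() < 1:
                continue
            est = select_and_refit(
                spec, catalog,
                threshold=config.signature_threshold,
                n_bootstrap=config.n_bootstrap,
                seed=config.seed,
            )
            df = est.as_frame()
            df.insert(0, "patient_id", patient)
            exposure_rows.append(df)
            selected_union |= {
                n for n, sel in zip(est.signatures, est.selected) if sel
            }
        if exposure_rows:
            pd.concat(exposure_rows).to_csv(
                outdir / "exposures.tsv", sep="\t", index=False
            )
        report["stages_run"].append("signatures")
        report["signatures"] = {
            "selected": sorted(cohort_selected),
            "selected_any_tumor": sorted(selected_union),
        }

    if config.enabled("enrich"):
        library = load_gmt(config.gmt, universe=_load_universe(config))
        prioritized = ranked[ranked["prioritized"]]["gene_id"].tolist()
        if prioritized:
            res = enrich(prioritized, library)
            res.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
            sub = config.subsampling
            size_min = min(int(sub.get("size_min", 5)), len(prioritized))
            sens = subsample_sensitivity(
                prioritized, library,
                n_subsamples=int(sub.get("n_subsamples", 200)),
                size_range=(size_min, int(sub.get("size_max", 20))),
                alpha=float(sub.get("alpha", 0.05)),
                seed=config.seed,
            )
            sens.proportions.to_csv(
                outdir / "sensitivity.tsv", sep="\t", index=False
            )
            sens.per_size.to_csv(
                outdir / "sensitivity_per_size.tsv", sep="\t", index=False
            )
            top = res.head(5)
            report["enrich"] = {
                "top_terms": [
                    {"set_name": r.set_name, "adjusted_p": r.adjusted_p}
                    for r in top.itertuples()
                ],
                "stable_terms": {
                    r.set_name: r.proportion_significant
                    for r in sens.proportions.itertuples()
                },
            }
        else:
            report["enrich"] = {"top_terms": [], "stable_terms": {}}
        report["stages_run"].append("enrich")

    if config.enabled("validate_external"):
        ec = config.external_counts
        counts = pd.read_csv(ec["table"], sep="\t")
        res = external_burden_test(
            counts,
            total_deceased=int(ec["total_deceased"]),
            total_alive=int(ec["total_alive"]),
            alpha=config.burden_alpha,
        )
        res.to_csv(outdir / "external_validation.tsv", sep="\t", index=False)
        report["stages_run"].append("validate_external")
        report["validate_external"] = {
            "n_genes": len(res),
            "n_significant": int(res["significant"].sum()),
            "significant_genes": res[res["significant"]]["gene_id"].tolist(),
        }

    rep = RunReport(report)
    rep.to_json(outdir / "run_report.json")
    return rep


def _default_exposures(catalog: SignatureCatalog) -> list[float]:
    """Three active signatures by default, echoing a typical tumor exome."""
    vec = [0.0] * catalog.n_signatures
    active = [0, 4, 11] if catalog.n_signatures >= 12 else list(
        range(min(3, catalog.n_signatures))
    )
    for i in active:
        vec[i] = 1.0 / len(active)
    return vec


def _load_labels(config: RunConfig) -> dict[str, str]:
    path = Path(config.outdir) / "labels.tsv"
    if not path.exists():
        raise ValueError(
            "no vital-status labels available: simulate stage disabled and "
            f"{path} not found"
        )
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["patient_id"], df["vital_status"]))


def _load_universe(config: RunConfig) -> set[str] | None:
    if not config.universe:
        return None
    return {
        line.strip() for line in Path(config.universe).read_text().splitlines()
        if line.strip()
    }
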
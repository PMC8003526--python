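"""End-to-end orchestration: calibration experiment and patient analysis.

``run_calibration_experiment`` simulates a titration set (two virtual cell
lines x tumor-fraction grid x replicates), estimates the TGF of every sample
in fixed-ploidy mode, scores agreement against the known truth, and fits the
logit-scale calibration model.  ``run_patient_analysis`` simulates (or
ingests) patient scenarios, estimates TGF in clinical mode (ploidy selected
on a grid), classifies CTMs, predicts calibrated TF with intervals for the
aberrant ones, and compares CNA profiles between CTMs and the matched tumor
fractions.  Everything is deterministic under the master seed, and every
output table carries a header with the package version, the seed and a
config hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .agreement import AgreementReport, agreement_report
from .calibration import CalibrationModel, MAECurve, fit_calibration, predict_tf
from .ctm_compare import (
    OverlapReport,
    PatientProfileSet,
    correlation_cluster,
    recurrent_ctm_private,
    shared_private_regions,
)
from .estimator import (
    CTM_ABERRANT,
    EstimatorConfig,
    TGFResult,
    classify_ctm,
    estimate_tgf,
    normalize_bins,
    uniform_reference,
)
from .genome import GenomeBins, build_genome_bins
from .simulate import (
    DEFAULT_READS_RANGE,
    DEFAULT_TF_GRID,
    PatientScenario,
    default_cell_lines,
    generate_patient_cohort,
    generate_titration_set,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of the full synthetic pipeline run."""

    master_seed: int = 1
    outdir: str | None = None
    # titration design
    tf_grid: tuple[float, ...] = DEFAULT_TF_GRID
    replicates: int = 3
    reads_range: tuple[int, int] = DEFAULT_READS_RANGE
    overdispersion: float | None = None
    # patient cohort
    n_patients: int = 6
    n_ctms_range: tuple[int, int] = (2, 14)
    # estimator
    estimator: EstimatorConfig = field(default_factory=EstimatorConfig)
    # calibration
    mae_anchors: tuple[tuple[float, float], ...] | None = None
    logit_eps: float = 0.005
    weight_rule: str = "inv"
    prediction_level: float = 0.95

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not self.tf_grid:
            raise ValueError("tf_grid must not be empty")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")

    @property
    def mae_curve(self) -> MAECurve:
        if self.mae_anchors is None:
            return MAECurve()
        return MAECurve(tuple(tuple(a) for a in self.mae_anchors))

    def config_hash(self) -> str:
        d = asdict(self)
        d.pop("outdir", None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        est = raw.pop("estimator", None)
        cfg = cls(**{k: _as_tuple(v) for k, v in raw.items()})
        if est:
            cfg.estimator = EstimatorConfig(**{k: _as_tuple(v) for k, v in est.items()})
        return cfg


def _as_tuple(v):
    if isinstance(v, list):
        return tuple(_as_tuple(x) for x in v)
    return v


@dataclass
class CalibrationExperimentReport:
    truth: pd.DataFrame
    tgf_table: pd.DataFrame
    agreement: AgreementReport
    model: CalibrationModel
    results: dict[str, TGFResult]


@dataclass
class PatientAnalysisReport:
    samples: pd.DataFrame            # per-sample TGF / class / TF predictions
    table2: pd.DataFrame             # stroma / T1 / T2 TGF per patient
    table3: pd.DataFrame             # shared/private fractions per patient
    consort: dict[str, int]
    overlap_reports: list[OverlapReport]
    recurrent_private: pd.DataFrame
    linkage_by_patient: dict[str, dict]
    scenarios: list[PatientScenario]


def _header_lines(config: RunConfig) -> str:
    return (
        f"# ctmtf v{__version__}\n"
        f"# seed={config.master_seed}\n"
        f"# config_hash={config.config_hash()}\n"
    )


def _write_table(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header_lines(config))
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def run_calibration_experiment(
    config: RunConfig, genome: GenomeBins | None = None
) -> CalibrationExperimentReport:
    """Simulate the titration, estimate TGF per sample, fit the calibration."""
    t0 = time.perf_counter()
    if genome is None:
        genome = build_genome_bins()
    cell_lines = default_cell_lines(genome)
    samples, truth = generate_titration_set(
        master_seed=config.master_seed,
        cell_lines=cell_lines,
        tf_grid=config.tf_grid,
        replicates=config.replicates,
        reads_range=config.reads_range,
        genome=genome,
        overdispersion=config.overdispersion,
    )
    logger.info("titration: %d samples simulated (%.1fs)", len(samples), time.perf_counter() - t0)

    ploidy_of = {cl.name: cl.target_mean_copy for cl in cell_lines}
    reference = uniform_reference(genome)
    rows = []
    results: dict[str, TGFResult] = {}
    for s in samples:
        cfg = config.estimator.fixed_ploidy(ploidy_of[s.cell_line])
        ratios = normalize_bins(s.counts, reference)
        res = estimate_tgf(ratios, cfg, sample_id=s.sample_id, aligned_reads=s.total_reads)
        results[s.sample_id] = res
        rows.append(
            {
                "sample_id": s.sample_id,
                "cell_line": s.cell_line,
                "replicate": s.replicate,
                "true_tf": s.true_tf,
                "tgf": res.tgf,
                "normal_fraction": res.normal_fraction,
                "ploidy": res.ploidy_used,
                "profile_class": res.profile_class,
                "qc_pass": res.qc_pass,
                "coverage": res.coverage,
            }
        )
    tgf_table = pd.DataFrame(rows)
    logger.info("titration: TGF estimated (%.1fs)", time.perf_counter() - t0)

    agreement = agreement_report(tgf_table, "true_tf", "tgf", group_col="cell_line")
    model = fit_calibration(
        tgf_table.rename(columns={})[["true_tf", "tgf", "coverage", "cell_line"]],
        curve=config.mae_curve,
        logit_eps=config.logit_eps,
        weight_rule=config.weight_rule,
    )
    logger.info(
        "calibration fit: a=%.4f b=%.4f su2=%.4g se2=%.4g (%.1fs)",
        model.intercept, model.slope, model.sigma_u2, model.sigma_e2,
        time.perf_counter() - t0,
    )

    if config.outdir:
        out = Path(config.outdir) / "calibration"
        _write_table(truth, out / "truth.tsv", config)
        _write_table(tgf_table, out / "tgf_titration.tsv", config)
        ba = agreement.ba
        ag_rows = [
            {"metric": "ccc_overall", "value": agreement.ccc_overall},
            *[
                {"metric": f"ccc_{g}", "value": v}
                for g, v in agreement.ccc_by_group.items()
            ],
            {"metric": "ba_mean_diff", "value": ba.mean_diff},
            {"metric": "ba_loa_low", "value": ba.loa_low},
            {"metric": "ba_loa_high", "value": ba.loa_high},
        ]
        _write_table(pd.DataFrame(ag_rows), out / "agreement.tsv", config)
        out.mkdir(parents=True, exist_ok=True)
        model.to_json(out / "model.json")
    return CalibrationExperimentReport(truth, tgf_table, agreement, model, results)


def run_patient_analysis(
    config: RunConfig,
    model: CalibrationModel,
    genome: GenomeBins | None = None,
) -> PatientAnalysisReport:
    """Estimate, classify and compare the synthetic patient cohort."""
    t0 = time.perf_counter()
    if genome is None:
        genome = build_genome_bins()
    scenarios = generate_patient_cohort(
        master_seed=config.master_seed,
        n_patients=config.n_patients,
        n_ctms_range=config.n_ctms_range,
        genome=genome,
        reads_range=config.reads_range,
    )
    reference = uniform_reference(genome)
    est_cfg = config.estimator
    rows = []
    results: dict[str, TGFResult] = {}
    ratios_by_sample: dict[str, object] = {}
    truth_tf = {}
    for sc in scenarios:
        for _, t in sc.truth.iterrows():
            truth_tf[t["sample_id"]] = float(t["true_tf"])
        for sid, counts in sc.counts.items():
            role = sc.truth.set_index("sample_id").loc[sid, "role"]
            total = int(counts.values.sum())
            if total < est_cfg.min_aligned_reads:
                rows.append(
                    {
                        "sample_id": sid, "patient_id": sc.patient_id, "role": role,
                        "true_tf": truth_tf[sid], "total_reads": total,
                        "qc_pass": False, "tgf": float("nan"),
                        "profile_class": "", "ctm_class": "",
                        "tf_hat": float("nan"), "pi_low": float("nan"),
                        "pi_high": float("nan"), "ci_low": float("nan"),
                        "ci_high": float("nan"), "coverage": float("nan"),
                    }
                )
                continue
            ratios = normalize_bins(counts, reference)
            ratios_by_sample[sid] = ratios
            res = estimate_tgf(ratios, est_cfg, sample_id=sid, aligned_reads=total)
            results[sid] = res
            row = {
                "sample_id": sid, "patient_id": sc.patient_id, "role": role,
                "true_tf": truth_tf[sid], "total_reads": total,
                "qc_pass": res.qc_pass, "tgf": res.tgf,
                "profile_class": res.profile_class,
                "ctm_class": "", "tf_hat": float("nan"),
                "pi_low": float("nan"), "pi_high": float("nan"),
                "ci_low": float("nan"), "ci_high": float("nan"),
                "coverage": res.coverage,
            }
            if role == "ctm":
                label = classify_ctm(res.tgf, res.profile_class, est_cfg)
                row["ctm_class"] = label
                if label == CTM_ABERRANT:
                    pred = predict_tf(
                        model, res.tgf, coverage=res.coverage,
                        level=config.prediction_level,
                    )
                    row.update(
                        tf_hat=pred.tf_hat, pi_low=pred.pi_low, pi_high=pred.pi_high,
                        ci_low=pred.ci_low, ci_high=pred.ci_high,
                    )
            rows.append(row)
    samples = pd.DataFrame(rows)
    logger.info("patients: %d samples estimated (%.1fs)", len(samples), time.perf_counter() - t0)

    # Table 2 style: stroma / T1 / T2 TGF per patient
    t2_rows = []
    for sc in scenarios:
        r = {"patient_id": sc.patient_id}
        for role_sid, col in [
            (sc.stroma.sample_id, "stroma_tgf"),
            (sc.tumor_t1.sample_id, "tumor1_tgf"),
            (sc.tumor_t2.sample_id, "tumor2_tgf"),
        ]:
            r[col] = results[role_sid].tgf if role_sid in results else float("nan")
        t2_rows.append(r)
    table2 = pd.DataFrame(t2_rows)

    # Table 3 style: shared/private fractions from the estimated profiles of
    # the tumor fractions and the aberrant CTMs
    overlap_reports: list[OverlapReport] = []
    t3_rows = []
    ctm_profiles_for_screen = []
    for sc in scenarios:
        aberrant_ids = samples.query(
            "patient_id == @sc.patient_id and ctm_class == @CTM_ABERRANT"
        )["sample_id"].tolist()
        if not aberrant_ids:
            logger.warning("%s: no aberrant CTMs; skipping overlap", sc.patient_id)
            continue
        pps = PatientProfileSet(
            patient_id=sc.patient_id,
            tumor_t2=results[sc.tumor_t2.sample_id].segments,
            tumor_t1=(
                results[sc.tumor_t1.sample_id].segments
                if sc.tumor_t1.sample_id in results
                else None
            ),
            ctms=[results[sid].segments for sid in aberrant_ids],
        )
        rep = shared_private_regions(pps, genome, est_cfg.exclude_chroms)
        overlap_reports.append(rep)
        ctm_profiles_for_screen.extend(results[sid].segments for sid in aberrant_ids)
        t3_rows.append(rep.as_row())
    table3 = pd.DataFrame(
        t3_rows,
        columns=["patient_id", "cna_private_tumor", "cna_private_ctm", "cna_shared"],
    )

    if len(overlap_reports) >= 2:
        recurrent = recurrent_ctm_private(
            overlap_reports, ctm_profiles_for_screen, genome,
            exclude_chroms=est_cfg.exclude_chroms,
        ).regions
    else:
        recurrent = pd.DataFrame(columns=["chrom", "start", "end", "type", "frequency"])

    # per-patient Pearson/complete-linkage clustering of tumor + CTM profiles
    linkage_by_patient: dict[str, dict] = {}
    for sc in scenarios:
        ids = [
            sid
            for sid in sc.counts
            if sid in ratios_by_sample
            and samples.set_index("sample_id").loc[sid, "role"] in ("tumor", "ctm")
        ]
        if len(ids) < 2:
            continue
        cc = correlation_cluster({sid: ratios_by_sample[sid] for sid in ids})
        linkage_by_patient[sc.patient_id] = {
            "sample_ids": cc.sample_ids,
            "linkage": np.asarray(cc.linkage_matrix).tolist(),
        }

    ctm_mask = samples["role"] == "ctm"
    consort = {
        "total_samples": int(len(samples)),
        "total_ctms": int(ctm_mask.sum()),
        "qc_failed": int((~samples.loc[ctm_mask, "qc_pass"]).sum()),
        "normal_ctms": int((samples["ctm_class"] == "Normal CTM").sum()),
        "unclear_ctms": int((samples["ctm_class"] == "Unclear CTM").sum()),
        "aberrant_ctms": int((samples["ctm_class"] == CTM_ABERRANT).sum()),
    }

    if config.outdir:
        out = Path(config.outdir) / "patients"
        _write_table(samples, out / "samples.tsv", config)
        _write_table(table2, out / "table2_tgf.tsv", config)
        _write_table(table3, out / "table3_overlap.tsv", config)
        _write_table(recurrent, out / "recurrent_ctm_private.tsv", config)
        _write_table(
            pd.DataFrame([consort]).T.reset_index().set_axis(["count", "value"], axis=1),
            out / "consort.tsv", config,
        )
        out.mkdir(parents=True, exist_ok=True)
        (out / "linkage.json").write_text(
            json.dumps(linkage_by_patient, indent=2, sort_keys=True) + "\n"
        )
    return PatientAnalysisReport(
        samples=samples,
        table2=table2,
        table3=table3,
        consort=consort,
        overlap_reports=overlap_reports,
        recurrent_private=recurrent,
        linkage_by_patient=linkage_by_patient,
        scenarios=scenarios,
    )


def run_all(
    config: RunConfig, genome: GenomeBins | None = None
) -> tuple[CalibrationExperimentReport, PatientAnalysisReport]:
    """Calibration experiment followed by patient analysis with its model."""
    if genome is None:
        genome = build_genome_bins()
    cal = run_calibration_experiment(config, genome)
    pat = run_patient_analysis(config, cal.model, genome)
    return cal, pat
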
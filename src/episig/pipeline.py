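"""End-to-end orchestration: simulate -> QC -> DMP -> DMR -> train -> predict.

One :class:`RunConfig` drives every stage with a single seed; every
intermediate artifact is persisted so a rerun with the same config and seed
reproduces all outputs byte-identically (timestamps excluded).  Cohort
splitting assigns a 75% training fraction of patients and carriers (floor
rounding, which reproduces the 7/3 patient and 6/2 carrier splits of a
10-patient, 8-carrier cohort); all matched controls stay in training.
"""

from __future__ import annotations

import json
import math
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .io_formats import (
    BetaMatrix,
    save_model,
    write_beta_matrix,
    write_dmr_bed,
    write_manifest,
    write_sample_sheet,
)
from .qc_preprocess import (
    beta_to_m,
    check_density_bimodality,
    check_sample_sex,
    estimate_cell_fractions,
    filter_probes,
    write_cell_reference,
)
from . import dmp as dmp_mod
from . import dmr as dmr_mod
from . import classifier as clf_mod
from . import synthetic_data as synth

__all__ = ["RunConfig", "RunReport", "split_cohort", "run_all", "example_run_config"]


@dataclass
class RunConfig:
    """Everything one pipeline run needs."""

    simulation: synth.SimulationConfig
    outdir: Path
    seed: int = 0
    train_fraction: float = 0.75
    detection_threshold: float = 0.01
    p_adj_cut: float = 0.01
    delta_cut: float = 0.10
    min_probes: int = 3
    bootstrap_B: int = 1000
    folds: int = 10
    run_dmr: bool = True
    run_classifier: bool = True
    run_external: bool = False
    n_external_controls: int = 500
    n_external_other: int = 587

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        for name in ("detection_threshold", "p_adj_cut", "delta_cut"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        self.outdir = Path(self.outdir)


@dataclass
class RunReport:
    seed: int
    version: str = __version__
    n_samples: int = 0
    probes_in: int = 0
    probes_after_qc: int = 0
    qc: dict = field(default_factory=dict)
    n_dmps: int = 0
    n_hypo: int = 0
    n_hyper: int = 0
    cluster_purity: float = float("nan")
    n_dmrs: Optional[int] = None
    n_after_auc: Optional[int] = None
    n_features: Optional[int] = None
    cv_accuracy: Optional[float] = None
    test_confusion: Optional[dict] = None
    specificity: Optional[float] = None
    wall_time_s: float = 0.0

    def to_json(self) -> str:
        payload = {k: v for k, v in asdict(self).items() if v is not None}
        for k, v in payload.items():
            if isinstance(v, float) and math.isnan(v):
                payload[k] = None
        return json.dumps(payload, indent=1)


def split_cohort(sheet: pd.DataFrame, train_fraction: float = 0.75, seed: int = 0) -> pd.DataFrame:
    """Stratified random training/testing split of patients and carriers.

    floor(train_fraction * n) of each of the patient and carrier groups are
    assigned to training and the remainder to testing; controls always train.
    """
    counts = sheet["group"].value_counts()
    if counts.get("patient", 0) < 4:
        raise ValueError("need at least 4 patients to split")
    if counts.get("carrier", 0) < 2:
        raise ValueError("need at least 2 carriers to split")
    rng = np.random.default_rng([seed, 7])
    out = sheet.copy()
    out["role"] = "training"
    for grp in ("patient", "carrier"):
        idx = out.index[out["group"] == grp].to_numpy()
        n_train = int(math.floor(train_fraction * len(idx)))
        shuffled = idx.copy()
        rng.shuffle(shuffled)
        out.loc[shuffled[n_train:], "role"] = "testing"
    return out


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc

        return inner

    return wrap


def run_all(config: RunConfig) -> RunReport:
    """Execute all configured stages, persisting every intermediate artifact."""
    t0 = time.monotonic()
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=config.seed)

    # -- simulate ------------------------------------------------------------
    sim = config.simulation
    manifest = _stage("simulate")(synth.generate_manifest)(sim)
    beta, sheet, truth = _stage("simulate")(synth.simulate_cohort)(sim, manifest)
    write_manifest(manifest, out / "manifest.tsv")
    write_beta_matrix(beta, out / "beta.tsv")
    (out / "truth.json").write_text(json.dumps(truth.to_dict(), indent=1))
    write_cell_reference(truth.cell_reference, out / "cell_reference.tsv")
    report.n_samples = beta.shape[1]
    report.probes_in = beta.shape[0]

    # -- qc ------------------------------------------------------------------
    @_stage("qc")
    def _qc():
        sex = check_sample_sex(beta, manifest, sheet)
        density = check_density_bimodality(beta)
        filtered, qc_report = filter_probes(
            beta, manifest, detection_threshold=config.detection_threshold
        )
        qc_report.samples_flagged_by["sex_discordance"] = list(sex.flagged)
        qc_report.samples_flagged_by["density"] = list(density.flagged)
        fractions = estimate_cell_fractions(beta, truth.cell_reference)
        return filtered, qc_report, fractions

    filtered, qc_report, fractions = _qc()
    (out / "qc_report.json").write_text(json.dumps(qc_report.to_dict(), indent=1))
    write_beta_matrix(filtered, out / "beta_qc.tsv")
    fractions.to_csv(out / "fractions.tsv", sep="\t", index_label="sample_id")
    report.probes_after_qc = filtered.shape[0]
    report.qc = qc_report.to_dict()

    # -- split ---------------------------------------------------------------
    sheet = _stage("split")(split_cohort)(sheet, config.train_fraction, config.seed)
    write_sample_sheet(sheet, out / "samples.csv")
    training = sheet[sheet["role"] == "training"]
    testing = sheet[sheet["role"] == "testing"]

    # -- dmp -----------------------------------------------------------------
    @_stage("dmp")
    def _dmp():
        design = dmp_mod.build_design(training, fractions)
        M = pd.DataFrame(
            beta_to_m(filtered.values.to_numpy()),
            index=filtered.probe_ids,
            columns=filtered.sample_ids,
        )
        fit = dmp_mod.fit_probe_models(M, design)
        _, stats_table = dmp_mod.ebayes_moderate(fit)
        train_beta = filtered.subset_samples(training["sample_id"])
        dmps = dmp_mod.call_dmps(
            stats_table, train_beta, training, config.p_adj_cut, config.delta_cut
        )
        return M, design, dmps

    M, design, dmps = _dmp()
    dmps.to_csv(out / "dmp.tsv", sep="\t")
    report.n_dmps = len(dmps)
    report.n_hypo = int((dmps["direction"] == "hypo").sum())
    report.n_hyper = int((dmps["direction"] == "hyper").sum())
    if len(dmps) >= 2:
        purity = _stage("dmp")(dmp_mod.signature_cluster_purity)(
            filtered.subset_samples(training["sample_id"]), training, dmps.index
        )
        report.cluster_purity = purity.purity

    # -- dmr -----------------------------------------------------------------
    if config.run_dmr:

        @_stage("dmr")
        def _dmr():
            man_qc = manifest[manifest["probe_id"].isin(filtered.probe_ids)].reset_index(drop=True)
            train_beta = filtered.subset_samples(training["sample_id"])
            delta = dmp_mod.group_mean_delta_beta(train_beta, training)
            cand = dmr_mod.find_candidate_regions(
                delta, man_qc, config.delta_cut, config.min_probes
            )
            dmrs = dmr_mod.bootstrap_fwer(
                M, design, cand, man_qc,
                B=config.bootstrap_B, seed=config.seed,
                effect_cut=config.delta_cut, min_probes=config.min_probes,
                delta_cut=config.delta_cut,
            )
            return dmr_mod.annotate_dmrs(dmrs, man_qc)

        dmrs = _dmr()
        dmrs.drop(columns="probe_ids").to_csv(out / "dmr.tsv", sep="\t", index=False)
        write_dmr_bed(dmrs, out / "dmr.bed")
        report.n_dmrs = len(dmrs)

    # -- classifier ----------------------------------------------------------
    if config.run_classifier and len(dmps) >= 2:

        @_stage("classifier")
        def _clf():
            train_beta = filtered.subset_samples(training["sample_id"])
            selection = clf_mod.select_features(train_beta, training, dmps.index)
            model = clf_mod.train_svm(
                train_beta, training, selection.retained_after_pruning,
                folds=config.folds, seed=config.seed,
            )
            return selection, model

        selection, model = _clf()
        save_model(model, out / "model.json")
        report.n_after_auc = len(selection.retained_after_auc)
        report.n_features = len(model.probe_ids)
        report.cv_accuracy = model.cv_accuracy

        if len(testing):
            test_beta = filtered.subset_samples(testing["sample_id"])
            scores = _stage("classifier")(clf_mod.predict_scores)(model, test_beta)
            scores.rename(columns={"ambiguous": "ambiguous_flag"}).to_csv(out / "scores.tsv", sep="\t")
            by = testing.set_index("sample_id")["group"]
            confusion = pd.crosstab(
                pd.Series([by[s] for s in scores.index], index=scores.index),
                scores["predicted_class"],
            )
            report.test_confusion = {
                truth_grp: {k: int(v) for k, v in row.items()}
                for truth_grp, row in confusion.iterrows()
            }

        if config.run_external:

            @_stage("external")
            def _ext():
                ext = synth.simulate_external_cohorts(
                    sim, manifest, model.probe_ids,
                    n_controls=config.n_external_controls,
                    n_other=config.n_external_other,
                )
                filt_ext = ext.beta.subset_probes(filtered.probe_ids)
                return clf_mod.evaluate_specificity(model, filt_ext, ext.sheet)

            spec = _ext()
            report.specificity = spec.specificity
            spec.scores.to_csv(out / "external_scores.tsv", sep="\t")

    report.wall_time_s = time.monotonic() - t0
    (out / "report.json").write_text(report.to_json())
    return report


def example_run_config(outdir, seed: int = 0, n_background: int = 3000) -> RunConfig:
    """A small but complete configuration exercising every stage."""
    effects = synth.signature_probe_effects(
        n_hypo=120, n_hyper=47, n_background_probes=n_background,
        magnitude_range=(0.15, 0.35), seed=seed,
    )
    sim = synth.SimulationConfig(
        n_background_probes=n_background,
        planted_probe_effects=effects,
        planted_regions=synth.default_dmr_geometry(),
        n_patients=10,
        n_carriers=8,
        n_controls=56,
        noise_sd=0.25,
        seed=seed,
    )
    return RunConfig(simulation=sim, outdir=Path(outdir), seed=seed, bootstrap_B=200)
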
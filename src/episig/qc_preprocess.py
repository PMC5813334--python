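"""Quality control and preprocessing of methylation beta matrices.

Implements the probe blacklist filters (failed detection, sex chromosomes,
SNP-overlapping and cross-reactive probes, missing values), two sample-level
sanity checks (labeled-vs-predicted sex concordance and genome-wide density
bimodality), the beta/M-value transform pair, and reference-based blood
cell-composition estimation by constrained projection.

The pipeline assumes its input beta matrix is already normalized; raw intensity
processing is upstream of this package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .io_formats import BetaMatrix, FormatError

__all__ = [
    "BETA_CLIP_EPS",
    "beta_to_m",
    "m_to_beta",
    "QcReport",
    "SexCheckResult",
    "DensityCheckResult",
    "filter_probes",
    "check_sample_sex",
    "check_density_bimodality",
    "CellTypeReference",
    "read_cell_reference",
    "write_cell_reference",
    "estimate_cell_fractions",
]

#: betas are clipped into [eps, 1 - eps] before the logit to avoid infinities
BETA_CLIP_EPS = 1e-3

PROBE_FILTER_RULES = ("detection", "xy", "snp", "crossreactive", "missing")


def beta_to_m(beta, eps: float = BETA_CLIP_EPS):
    """M = log2(beta / (1 - beta)), with beta clipped to [eps, 1 - eps]."""
    b = np.clip(np.asarray(beta, dtype=float), eps, 1.0 - eps)
    return np.log2(b / (1.0 - b))


def m_to_beta(m):
    """Inverse of :func:`beta_to_m`: beta = 2^M / (1 + 2^M)."""
    m = np.asarray(m, dtype=float)
    # expm1-style stable logistic in base 2
    out = np.empty_like(m, dtype=float)
    pos = m >= 0
    out[pos] = 1.0 / (1.0 + np.exp2(-m[pos]))
    e = np.exp2(m[~pos])
    out[~pos] = e / (1.0 + e)
    return out


@dataclass
class QcReport:
    """Counts of probes removed per rule and ids of flagged samples.

    Each removed probe is attributed to the first rule that matched it, in the
    fixed order detection -> xy -> snp -> crossreactive -> missing.
    """

    probes_removed_by: dict = field(default_factory=dict)
    samples_flagged_by: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    @property
    def n_probes_removed(self) -> int:
        return int(sum(self.probes_removed_by.values()))

    def to_dict(self) -> dict:
        return {
            "probes_removed_by": {k: int(v) for k, v in self.probes_removed_by.items()},
            "samples_flagged_by": {
                k: list(map(str, v)) for k, v in self.samples_flagged_by.items()
            },
            "warnings": list(self.warnings),
        }


def filter_probes(
    beta: BetaMatrix,
    manifest: pd.DataFrame,
    detection_threshold: float = 0.01,
    max_fail_fraction: float = 0.0,
) -> tuple[BetaMatrix, QcReport]:
    """Apply the probe blacklist filters, in order, and report counts per rule.

    Removal order (first matching rule claims the probe):

    1. detection p > ``detection_threshold`` in more than ``max_fail_fraction``
       of samples (default 0: any failing sample removes the probe), when a
       detection matrix is present;
    2. probes flagged on chromosomes X/Y;
    3. probes overlapping SNPs;
    4. cross-reactive probes;
    5. probes with any missing beta.
    """
    manifest = manifest.set_index("probe_id")
    unknown = beta.probe_ids.difference(manifest.index)
    if len(unknown):
        raise FormatError(
            f"{len(unknown)} probes in beta matrix absent from manifest, "
            f"e.g. {unknown[:3].tolist()}"
        )
    flags = manifest.loc[beta.probe_ids]

    removed = pd.Series(False, index=beta.probe_ids)
    counts: dict[str, int] = {}

    def claim(rule: str, mask: pd.Series) -> None:
        new = mask & ~removed
        counts[rule] = int(new.sum())
        removed[new] = True

    if beta.detection_p is not None:
        fail_frac = (beta.detection_p > detection_threshold).mean(axis=1)
        claim("detection", fail_frac > max_fail_fraction)
    else:
        counts["detection"] = 0
    claim("xy", flags["flag_xy"])
    claim("snp", flags["flag_snp"])
    claim("crossreactive", flags["flag_crossreactive"])
    claim("missing", beta.values.isna().any(axis=1))

    keep = beta.probe_ids[~removed]
    report = QcReport(probes_removed_by=counts)
    return beta.subset_probes(keep), report


@dataclass
class SexCheckResult:
    predicted_sex: pd.Series  # per sample: "M", "F", or "unknown"
    flagged: list  # samples whose predicted sex disagrees with the label
    warning: Optional[str] = None

    def as_report(self) -> QcReport:
        rep = QcReport(samples_flagged_by={"sex_discordance": list(self.flagged)})
        if self.warning:
            rep.warnings.append(self.warning)
        return rep


def check_sample_sex(
    beta: BetaMatrix,
    manifest: pd.DataFrame,
    sheet: pd.DataFrame,
    mid_low: float = 0.25,
    mid_high: float = 0.75,
    female_mid_fraction: float = 0.20,
) -> SexCheckResult:
    """Predict sample sex from chrX methylation and flag label discordance.

    X inactivation leaves a large share of chrX probes at intermediate
    methylation in females, while males are near the bimodal extremes.  A
    sample is predicted female when the fraction of its chrX betas inside
    [mid_low, mid_high] is at least ``female_mid_fraction``.  Must run before
    X/Y probes are filtered out.
    """
    chrx = manifest.loc[
        manifest["chrom"].astype(str).str.upper().isin(["CHRX", "X"]), "probe_id"
    ]
    chrx = beta.probe_ids.intersection(chrx)
    labels = sheet.set_index("sample_id")["labeled_sex"]
    if len(chrx) == 0:
        warn = "no chrX probes in manifest; sex prediction skipped"
        warnings.warn(warn)
        pred = pd.Series("unknown", index=beta.sample_ids)
        return SexCheckResult(pred, [], warning=warn)
    sub = beta.values.loc[chrx]
    mid = ((sub > mid_low) & (sub < mid_high)).mean(axis=0)
    pred = pd.Series(np.where(mid >= female_mid_fraction, "F", "M"), index=beta.sample_ids)
    flagged = [
        s for s in beta.sample_ids if s in labels.index and pred[s] != labels[s]
    ]
    return SexCheckResult(pred, flagged)


@dataclass
class DensityCheckResult:
    mid_fraction: pd.Series
    flagged: list

    def as_report(self) -> QcReport:
        return QcReport(samples_flagged_by={"density": list(self.flagged)})


def check_density_bimodality(
    beta: BetaMatrix,
    mid_low: float = 0.3,
    mid_high: float = 0.7,
    max_mid_fraction: float = 0.35,
) -> DensityCheckResult:
    """Flag samples whose genome-wide beta density is not bimodal.

    Healthy methylomes concentrate near 0 and 1; a sample is flagged when more
    than ``max_mid_fraction`` of its betas fall in (mid_low, mid_high).
    Requires at least 100 probes for the density to be meaningful.
    """
    if beta.shape[0] < 100:
        raise ValueError("density check needs at least 100 probes")
    mid = ((beta.values > mid_low) & (beta.values < mid_high)).mean(axis=0)
    flagged = beta.sample_ids[mid > max_mid_fraction].tolist()
    return DensityCheckResult(mid, flagged)


@dataclass
class CellTypeReference:
    """Reference beta profiles of blood cell types at marker probes.

    ``betas`` is a DataFrame of reference methylation fractions indexed by
    marker probe id with one column per cell type.
    """

    betas: pd.DataFrame

    def __post_init__(self) -> None:
        if self.betas.shape[1] < 2:
            raise FormatError("cell-type reference needs at least 2 cell types")
        if self.betas.index.has_duplicates:
            raise FormatError("duplicate marker probe ids in cell-type reference")
        vals = self.betas.to_numpy()
        if vals.min() < 0 or vals.max() > 1:
            raise FormatError("cell-type reference betas must lie in [0, 1]")

    @property
    def cell_types(self) -> list:
        return list(self.betas.columns)

    @property
    def marker_ids(self) -> pd.Index:
        return self.betas.index


def read_cell_reference(path) -> CellTypeReference:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    return CellTypeReference(df.astype(float))


def write_cell_reference(ref: CellTypeReference, path) -> None:
    ref.betas.to_csv(path, sep="\t", index_label="probe_id")


def _project_fractions(y: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Least squares of y against columns of R s.t. x >= 0 and sum(x) = 1."""
    k = R.shape[1]
    x0 = np.full(k, 1.0 / k)
    res = minimize(
        lambda x: 0.5 * np.sum((R @ x - y) ** 2),
        x0,
        jac=lambda x: R.T @ (R @ x - y),
        bounds=[(0.0, 1.0)] * k,
        constraints=[{"type": "eq", "fun": lambda x: x.sum() - 1.0}],
        method="SLSQP",
        options={"maxiter": 200, "ftol": 1e-12},
    )
    x = np.clip(res.x, 0.0, None)
    return x / x.sum()


def estimate_cell_fractions(beta: BetaMatrix, reference: CellTypeReference) -> pd.DataFrame:
    """Estimate per-sample blood cell-type fractions by constrained projection.

    Solves, per sample, a least-squares fit of the sample's marker-probe betas
    against the reference profiles subject to non-negativity and sum-to-one
    (Houseman-style constrained projection).  Returns samples x cell types.
    """
    shared = beta.probe_ids.intersection(reference.marker_ids)
    k = len(reference.cell_types)
    if len(shared) < k:
        raise ValueError(
            f"only {len(shared)} marker probes shared with the reference; "
            f"need at least {k}"
        )
    # sort for order invariance with respect to the incoming probe order
    shared = shared.sort_values()
    R = reference.betas.loc[shared].to_numpy()
    Y = beta.values.loc[shared].to_numpy()
    out = np.vstack([_project_fractions(Y[:, j], R) for j in range(Y.shape[1])])
    return pd.DataFrame(out, index=beta.sample_ids, columns=reference.cell_types)
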
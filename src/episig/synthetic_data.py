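"""Synthetic methylation-array cohorts with a planted epi-signature.

The generator emulates the features of peripheral-blood 450k data that the
downstream stages depend on: bimodal beta densities, CpG probes clustered into
island-like groups separated by >500 bp gaps, blood cell-type mixtures, a
planted patient signature (per-probe and regional effects of >=10% beta
difference), and a carrier class expressing a configurable fraction of the
patient effect (default one half, motivated by mosaic dosage of an X-linked
gene that escapes inactivation in heterozygous females).

Noise is logit-normal: sample betas are the logistic of the group mean's
M-value plus Gaussian noise in M units, which keeps the beta/M transforms
exact and the bimodal shape easy to control.  All draws flow from a single
seed through per-stage substreams, so cohorts are bitwise reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import BetaMatrix, sort_manifest, validate_manifest, validate_sample_sheet
from .qc_preprocess import CellTypeReference, beta_to_m, m_to_beta

__all__ = [
    "PlantedRegion",
    "SimulationConfig",
    "SyntheticTruth",
    "ExternalCohort",
    "BLOOD_CELL_TYPES",
    "BASE_CELL_FRACTIONS",
    "DEFAULT_DMR_GEOMETRY",
    "default_dmr_geometry",
    "signature_probe_effects",
    "generate_manifest",
    "simulate_cohort",
    "simulate_external_cohorts",
]

MAX_DETECTABLE_GAP = 500  # bp; region-defining gap rule

BLOOD_CELL_TYPES = ("neutrophil", "cd4t", "cd8t", "bcell", "monocyte", "nk")
BASE_CELL_FRACTIONS = (0.55, 0.15, 0.10, 0.08, 0.08, 0.04)

# substream tags for the single global seed
_STREAM_MANIFEST = 1
_STREAM_BASE = 2
_STREAM_COHORT = 3
_STREAM_EXTERNAL = 4


@dataclass(frozen=True)
class PlantedRegion:
    """A contiguous run of probes sharing one signed regional beta shift."""

    chrom: str
    start: int  # 1-based inclusive
    end: int
    n_probes: int
    delta_beta: float

    @property
    def width(self) -> int:
        return self.end - self.start + 1


#: Nine-region geometry used throughout: genomic spans (1-based inclusive),
#: signed regional beta differences (patients minus controls; one region
#: hypermethylated) and per-region probe counts consistent with the spans
#: under the <=500 bp inter-probe gap rule.
DEFAULT_DMR_GEOMETRY = (
    PlantedRegion("chr15", 89_919_993, 89_921_182, 8, +0.288),
    PlantedRegion("chr17", 7_486_551, 7_486_874, 3, -0.297),
    PlantedRegion("chr6", 164_092_410, 164_093_099, 6, -0.326),
    PlantedRegion("chr13", 113_242_878, 113_243_141, 3, -0.333),
    PlantedRegion("chr2", 25_383_404, 25_384_809, 7, -0.267),
    PlantedRegion("chr5", 176_559_334, 176_559_563, 3, -0.333),
    PlantedRegion("chr2", 232_348_334, 232_348_794, 4, -0.284),
    PlantedRegion("chr1", 7_887_199, 7_887_560, 5, -0.245),
    PlantedRegion("chr16", 2_801_793, 2_801_952, 3, -0.313),
)


def default_dmr_geometry() -> list:
    return list(DEFAULT_DMR_GEOMETRY)


@dataclass
class SimulationConfig:
    """Parameters of one synthetic cohort.

    Defaults reproduce the discovery/training study conditions: 7 patients,
    6 carriers and 56 matched controls, carriers expressing half the patient
    effect, logit-normal noise with sd 0.35 in M units, and a six-cell-type
    blood mixture.
    """

    n_background_probes: int = 20_000
    planted_probe_effects: list = field(default_factory=list)  # [(bg index, delta)]
    planted_regions: list = field(default_factory=list)  # [PlantedRegion]
    n_patients: int = 7
    n_carriers: int = 6
    n_controls: int = 56
    carrier_factor: float = 0.5
    noise_sd: float = 0.35  # sd of logit-normal noise, M-value units
    n_chrx_probes: int = 200
    snp_flag_rate: float = 0.002
    crossreactive_flag_rate: float = 0.002
    cell_types: tuple = BLOOD_CELL_TYPES
    markers_per_cell_type: int = 10
    dirichlet_concentration: float = 60.0
    confounded_cell_fractions: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.carrier_factor <= 1.0:
            raise ValueError("carrier_factor must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for idx, delta in self.planted_probe_effects:
            if not 0 <= idx < self.n_background_probes:
                raise ValueError(f"planted probe index {idx} out of range")
            if abs(delta) > 1:
                raise ValueError(f"|delta beta| must be <= 1, got {delta}")
        for region in self.planted_regions:
            if region.n_probes < 1:
                raise ValueError("planted regions need at least 1 probe")
            if abs(region.delta_beta) > 1:
                raise ValueError("regional |delta beta| must be <= 1")

    @property
    def n_samples(self) -> int:
        return self.n_patients + self.n_carriers + self.n_controls


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated cohort."""

    control_mean: pd.Series  # per probe
    patient_delta: pd.Series  # per probe, 0 for null probes
    regions: list  # PlantedRegion (with realized probe ids in region_probes)
    region_probes: dict  # region index -> list of probe ids
    cell_fractions: pd.DataFrame  # samples x cell types
    cell_reference: CellTypeReference
    carrier_factor: float

    @property
    def carrier_delta(self) -> pd.Series:
        # carriers express exactly carrier_factor times the patient effect
        return self.carrier_factor * self.patient_delta

    @property
    def signature_probes(self) -> list:
        return self.patient_delta.index[self.patient_delta != 0].tolist()

    def to_dict(self) -> dict:
        planted = self.patient_delta[self.patient_delta != 0]
        return {
            "carrier_factor": self.carrier_factor,
            "planted_probe_deltas": {k: float(v) for k, v in planted.items()},
            "regions": [
                {
                    "chrom": r.chrom,
                    "start": r.start,
                    "end": r.end,
                    "n_probes": r.n_probes,
                    "delta_beta": r.delta_beta,
                    "probe_ids": self.region_probes[i],
                }
                for i, r in enumerate(self.regions)
            ],
            "cell_fractions": {
                s: [float(x) for x in row]
                for s, row in self.cell_fractions.iterrows()
            },
        }


def signature_probe_effects(
    n_hypo: int,
    n_hyper: int,
    n_background_probes: int,
    magnitude_range: tuple = (0.12, 0.35),
    seed: int = 0,
) -> list:
    """Scatter a per-probe signature over the background probes.

    Returns (index, signed delta) pairs: ``n_hypo`` negative and ``n_hyper``
    positive effects with magnitudes drawn uniformly from
    ``magnitude_range``, at distinct probe indices.
    """
    n = n_hypo + n_hyper
    if n > n_background_probes:
        raise ValueError("more signature probes requested than background probes")
    rng = np.random.default_rng([seed, 99])
    idx = rng.choice(n_background_probes, size=n, replace=False)
    mags = rng.uniform(magnitude_range[0], magnitude_range[1], size=n)
    signs = np.concatenate([-np.ones(n_hypo), np.ones(n_hyper)])
    return [(int(i), float(s * m)) for i, s, m in zip(idx, signs, mags)]


def _region_positions(region: PlantedRegion) -> np.ndarray:
    if region.n_probes > region.width + 1:
        raise ValueError(
            f"region {region.chrom}:{region.start}-{region.end} cannot hold "
            f"{region.n_probes} probes"
        )
    pos = np.unique(np.round(np.linspace(region.start, region.end, region.n_probes)))
    pos = pos.astype(int)
    if len(pos) != region.n_probes:
        raise ValueError("region probe count incompatible with region width")
    if region.n_probes > 1 and int(np.diff(pos).max()) > MAX_DETECTABLE_GAP:
        raise ValueError(
            f"region {region.chrom}:{region.start}-{region.end} with "
            f"{region.n_probes} probes needs gaps > {MAX_DETECTABLE_GAP} bp; "
            "increase the probe count or shrink the region"
        )
    return pos


_BACKGROUND_CHROMS = tuple(f"chr{i}" for i in range(1, 23))
_BACKGROUND_OFFSET = 200_000_000  # keeps background clear of planted coordinates


def generate_manifest(config: SimulationConfig) -> pd.DataFrame:
    """Build a probe manifest realizing the configured geometry.

    Background probes are laid out in clusters (intra-cluster gaps < 500 bp,
    inter-cluster gaps >= 600 bp) across the autosomes; planted regions are
    realized as evenly spaced probe runs inside their genomic span; chrX
    probes (flagged for removal at QC) support the sex check; cell-type
    marker probes are isolated open-sea singletons.
    """
    rng = np.random.default_rng([config.seed, _STREAM_MANIFEST])
    rows = []

    # -- background clusters -------------------------------------------------
    per_chrom = np.full(len(_BACKGROUND_CHROMS), config.n_background_probes // len(_BACKGROUND_CHROMS))
    per_chrom[: config.n_background_probes % len(_BACKGROUND_CHROMS)] += 1
    probe_no = 0
    for chrom, target in zip(_BACKGROUND_CHROMS, per_chrom):
        pos = _BACKGROUND_OFFSET
        placed = 0
        while placed < target:
            size = min(int(rng.integers(1, 9)), target - placed)
            for i in range(size):
                if i > 0:
                    gap = int(rng.integers(455, MAX_DETECTABLE_GAP + 1)) if rng.random() < 0.1 else int(rng.integers(30, 451))
                    pos += gap
                if size >= 3:
                    relation = "island" if 0 < i < size - 1 else "shore"
                elif size == 2:
                    relation = "shelf"
                else:
                    relation = "open_sea"
                rows.append((f"bg{probe_no:06d}", chrom, pos, relation, False, False, False))
                probe_no += 1
                placed += 1
            pos += int(rng.integers(600, 5001))

    # -- planted regions -----------------------------------------------------
    for r_idx, region in enumerate(config.planted_regions):
        for p_idx, pos in enumerate(_region_positions(region)):
            rows.append(
                (f"dmr{r_idx:02d}_{p_idx:02d}", region.chrom, int(pos), "island", False, False, False)
            )

    # -- chrX probes (sex check; removed at QC) ------------------------------
    for i in range(config.n_chrx_probes):
        rows.append((f"chrXp{i:04d}", "chrX", 1_000_000 + 1000 * i, "open_sea", True, False, False))

    # -- cell-type marker probes ---------------------------------------------
    n_markers = len(config.cell_types) * config.markers_per_cell_type
    for i in range(n_markers):
        rows.append((f"cellmk{i:03d}", "chr19", _BACKGROUND_OFFSET + 100_000_000 + 2000 * i, "open_sea", False, False, False))

    manifest = pd.DataFrame(
        rows,
        columns=["probe_id", "chrom", "pos", "island_relation", "flag_xy", "flag_snp", "flag_crossreactive"],
    )

    # -- SNP / cross-reactive flags on background probes only ----------------
    planted_idx = {i for i, _ in config.planted_probe_effects}
    eligible = np.array(
        [i for i in range(config.n_background_probes) if i not in planted_idx]
    )
    bg_mask = manifest["probe_id"].str.startswith("bg")
    for rate, col in ((config.snp_flag_rate, "flag_snp"), (config.crossreactive_flag_rate, "flag_crossreactive")):
        n_flag = int(round(rate * config.n_background_probes))
        if n_flag and len(eligible):
            chosen = rng.choice(eligible, size=min(n_flag, len(eligible)), replace=False)
            ids = {f"bg{i:06d}" for i in chosen}
            manifest.loc[bg_mask & manifest["probe_id"].isin(ids), col] = True

    return validate_manifest(manifest)


@dataclass
class _BaseState:
    control_mean: pd.Series
    patient_delta: pd.Series
    region_probes: dict
    marker_profiles: pd.DataFrame  # markers x cell types
    male_x_mean: pd.Series
    female_x_mean: pd.Series
    marker_rows: np.ndarray
    chrx_rows: np.ndarray


def _draw_base_mean(rng: np.random.Generator, n: int) -> np.ndarray:
    """Bimodal control methylation: low and high modes plus a mid minority."""
    u = rng.uniform(size=n)
    low = rng.beta(2.5, 20.0, size=n)
    high = rng.beta(20.0, 2.5, size=n)
    mid = rng.uniform(0.25, 0.75, size=n)
    out = np.where(u < 0.45, low, np.where(u < 0.90, high, mid))
    return np.clip(out, 0.001, 0.999)


def _planted_base(rng: np.random.Generator, delta: float) -> float:
    """A control-mean baseline leaving headroom for a shift of ``delta``."""
    if delta < 0:
        lo = max(0.60, abs(delta) + 0.10)
        return float(rng.uniform(lo, 0.92))
    return float(rng.uniform(0.08, min(0.35, 0.94 - delta)))


def _base_state(config: SimulationConfig, manifest: pd.DataFrame) -> _BaseState:
    """Deterministic per-probe ground state shared by all cohorts of a config."""
    rng = np.random.default_rng([config.seed, _STREAM_BASE])
    probe_ids = manifest["probe_id"].to_numpy()
    n = len(probe_ids)
    mean = _draw_base_mean(rng, n)
    delta = np.zeros(n)

    pos_of = pd.Series(np.arange(n), index=probe_ids)
    for idx, d in config.planted_probe_effects:
        row = pos_of[f"bg{idx:06d}"]
        delta[row] = d
        mean[row] = _planted_base(rng, d)
    region_probes: dict = {}
    for r_idx, region in enumerate(config.planted_regions):
        ids = [f"dmr{r_idx:02d}_{i:02d}" for i in range(region.n_probes)]
        region_probes[r_idx] = ids
        base = _planted_base(rng, region.delta_beta)
        for pid in ids:
            row = pos_of[pid]
            delta[row] = region.delta_beta
            # members share one baseline plus slight probe-level wiggle
            mean[row] = np.clip(base + rng.uniform(-0.03, 0.03), 0.05, 0.95)

    chrx_rows = np.flatnonzero(manifest["chrom"].to_numpy() == "chrX")
    male_x = _draw_base_mean(rng, len(chrx_rows))
    # drop the mid component for males: push intermediates to the extremes
    male_x = np.where((male_x > 0.3) & (male_x < 0.7), np.where(male_x < 0.5, 0.08, 0.92), male_x)
    female_x = rng.uniform(0.35, 0.65, size=len(chrx_rows))
    mean[chrx_rows] = male_x  # default; per-sample override by sex at draw time

    marker_rows = np.flatnonzero(pd.Series(probe_ids).str.startswith("cellmk").to_numpy())
    k = len(config.cell_types)
    mk = config.markers_per_cell_type
    profiles = np.full((len(marker_rows), k), 0.15) + rng.uniform(-0.05, 0.05, size=(len(marker_rows), k))
    for t in range(k):
        own = slice(t * mk, (t + 1) * mk)
        profiles[own, t] = 0.85 + rng.uniform(-0.05, 0.05, size=mk)
    marker_ids = probe_ids[marker_rows]
    mean[marker_rows] = profiles @ np.asarray(BASE_CELL_FRACTIONS[:k]) / sum(BASE_CELL_FRACTIONS[:k])

    return _BaseState(
        control_mean=pd.Series(mean, index=probe_ids),
        patient_delta=pd.Series(delta, index=probe_ids),
        region_probes=region_probes,
        marker_profiles=pd.DataFrame(profiles, index=marker_ids, columns=list(config.cell_types)),
        male_x_mean=pd.Series(male_x, index=probe_ids[chrx_rows]),
        female_x_mean=pd.Series(female_x, index=probe_ids[chrx_rows]),
        marker_rows=marker_rows,
        chrx_rows=chrx_rows,
    )


def _draw_fractions(
    rng: np.random.Generator, config: SimulationConfig, groups: Sequence[str]
) -> np.ndarray:
    k = len(config.cell_types)
    base = np.asarray(BASE_CELL_FRACTIONS[:k], dtype=float)
    base = base / base.sum()
    shifted = base.copy()
    if config.confounded_cell_fractions:
        shifted[0] += 0.15  # neutrophilia in cases exercises the adjustment
        shifted = shifted / shifted.sum()
    out = np.empty((len(groups), k))
    for i, g in enumerate(groups):
        alpha = shifted if (config.confounded_cell_fractions and g in ("patient", "carrier")) else base
        out[i] = rng.dirichlet(config.dirichlet_concentration * alpha)
    return out


def _assemble_betas(
    config: SimulationConfig,
    state: _BaseState,
    rng: np.random.Generator,
    sample_ids: Sequence[str],
    dose: np.ndarray,
    sexes: Sequence[str],
    fractions: np.ndarray,
    extra_delta: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Per-sample group means -> logit-normal noise -> beta matrix."""
    n_probes = len(state.control_mean)
    base = state.control_mean.to_numpy()
    delta = state.patient_delta.to_numpy()
    # realized patient shift after clipping; carriers get exactly the
    # carrier_factor multiple of the realized shift
    realized = np.clip(base + delta, 0.001, 0.999) - base
    mean = base[:, None] + realized[:, None] * dose[None, :]
    if extra_delta is not None:
        mean = np.clip(mean + extra_delta, 0.001, 0.999)
    # chrX probes depend on sex, not group
    female = np.array([s == "F" for s in sexes])
    mean[np.ix_(state.chrx_rows, female)] = state.female_x_mean.to_numpy()[:, None]
    mean[np.ix_(state.chrx_rows, ~female)] = state.male_x_mean.to_numpy()[:, None]
    # marker probes are cell-type mixtures
    mean[state.marker_rows] = state.marker_profiles.to_numpy() @ fractions.T
    mean = np.clip(mean, 0.001, 0.999)
    if config.noise_sd > 0:
        m = beta_to_m(mean, eps=1e-6) + config.noise_sd * rng.standard_normal(mean.shape)
        betas = m_to_beta(m)
    else:
        betas = mean
    return pd.DataFrame(betas, index=state.control_mean.index, columns=list(sample_ids))


def simulate_cohort(
    config: SimulationConfig, manifest: pd.DataFrame
) -> tuple[BetaMatrix, pd.DataFrame, SyntheticTruth]:
    """Simulate a patient/carrier/control cohort on a generated manifest.

    Patients (males) carry the full planted effect, carriers (females)
    ``carrier_factor`` times the effect, controls (males, matched) none.
    Returns the beta matrix, the sample sheet, and the ground truth.
    """
    state = _base_state(config, manifest)
    rng = np.random.default_rng([config.seed, _STREAM_COHORT])

    sample_ids = (
        [f"pat{i + 1:02d}" for i in range(config.n_patients)]
        + [f"car{i + 1:02d}" for i in range(config.n_carriers)]
        + [f"ctl{i + 1:03d}" for i in range(config.n_controls)]
    )
    groups = (
        ["patient"] * config.n_patients
        + ["carrier"] * config.n_carriers
        + ["control"] * config.n_controls
    )
    sexes = ["M"] * config.n_patients + ["F"] * config.n_carriers + ["M"] * config.n_controls
    dose = np.array(
        [1.0] * config.n_patients
        + [config.carrier_factor] * config.n_carriers
        + [0.0] * config.n_controls
    )
    ages = np.concatenate(
        [
            rng.normal(21, 14, config.n_patients),
            rng.normal(40, 17, config.n_carriers),
            rng.normal(19, 12, config.n_controls),
        ]
    )
    fractions = _draw_fractions(rng, config, groups)
    values = _assemble_betas(config, state, rng, sample_ids, dose, sexes, fractions)

    sheet = validate_sample_sheet(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "labeled_sex": sexes,
                "group": groups,
                "age": np.clip(np.round(ages), 1, 80).astype(int),
                "role": "training",
            }
        )
    )
    base = state.control_mean.to_numpy()
    realized = np.clip(base + state.patient_delta.to_numpy(), 0.001, 0.999) - base
    truth = SyntheticTruth(
        control_mean=state.control_mean,
        patient_delta=pd.Series(realized, index=state.control_mean.index),
        regions=list(config.planted_regions),
        region_probes=state.region_probes,
        cell_fractions=pd.DataFrame(
            fractions, index=sample_ids, columns=list(config.cell_types)
        ),
        cell_reference=CellTypeReference(state.marker_profiles.copy()),
        carrier_factor=config.carrier_factor,
    )
    return BetaMatrix(values), sheet, truth


@dataclass
class ExternalCohort:
    """A specificity cohort: unaffected controls plus an unrelated disorder."""

    beta: BetaMatrix
    sheet: pd.DataFrame
    other_disorder_probes: list


def simulate_external_cohorts(
    config: SimulationConfig,
    manifest: pd.DataFrame,
    signature_probes: Sequence[str],
    n_controls: int = 500,
    n_other: int = 587,
    n_other_probes: int = 500,
    other_effect_range: tuple = (0.15, 0.35),
    other_probes: Optional[Sequence[str]] = None,
) -> ExternalCohort:
    """Simulate external controls plus samples with a disjoint epi-signature.

    The "other-disorder" samples carry a planted signature of comparable
    magnitude on probes chosen disjoint from ``signature_probes`` (and from
    the cohort's own planted probes), emulating patients with unrelated
    conditions that must not trigger the classifier.
    """
    state = _base_state(config, manifest)
    rng = np.random.default_rng([config.seed, _STREAM_EXTERNAL])
    signature = set(map(str, signature_probes))

    base = state.control_mean
    planted = set(state.patient_delta.index[state.patient_delta != 0])
    probe_ids = pd.Series(base.index)
    eligible = base.index[
        probe_ids.str.startswith("bg").to_numpy()
        & ~base.index.isin(signature | planted)
    ]
    if other_probes is None:
        if n_other_probes > len(eligible):
            raise ValueError("not enough background probes for the other-disorder signature")
        other_probes = list(rng.choice(eligible, size=n_other_probes, replace=False))
    else:
        other_probes = list(map(str, other_probes))
        overlap = sorted(set(other_probes) & (signature | planted))
        if overlap:
            raise ValueError(
                f"other-disorder probes overlap the signature: {overlap[:5]}"
            )

    mags = rng.uniform(other_effect_range[0], other_effect_range[1], size=len(other_probes))
    rows = base.index.get_indexer(other_probes)
    toward_center = np.where(base.to_numpy()[rows] < 0.5, 1.0, -1.0)
    other_delta_col = np.zeros(len(base))
    other_delta_col[rows] = toward_center * mags

    sample_ids = [f"extctl{i + 1:04d}" for i in range(n_controls)] + [
        f"oth{i + 1:04d}" for i in range(n_other)
    ]
    groups = ["control"] * n_controls + ["unknown"] * n_other
    sexes = list(rng.choice(["M", "F"], size=n_controls + n_other))
    dose = np.zeros(n_controls + n_other)
    extra = np.zeros((len(base), n_controls + n_other))
    extra[:, n_controls:] = other_delta_col[:, None]
    fractions = _draw_fractions(rng, config, groups)
    values = _assemble_betas(
        config, state, rng, sample_ids, dose, sexes, fractions, extra_delta=extra
    )
    sheet = validate_sample_sheet(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "labeled_sex": sexes,
                "group": groups,
                "age": np.clip(np.round(rng.normal(25, 15, len(sample_ids))), 1, 80).astype(int),
                "role": "external",
            }
        )
    )
    return ExternalCohort(BetaMatrix(values), sheet, list(map(str, other_probes)))
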
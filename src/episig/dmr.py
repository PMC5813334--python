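"""Bump-hunting detection of differentially methylated regions (DMRs).

Probes are grouped into genomic clusters (inter-probe gaps of at most 500 bp),
candidate regions are maximal same-sign runs of at least three consecutive
probes whose beta-scale effect exceeds 10%, and region significance is a
family-wise error rate estimated by a residual bootstrap: the null model
(design without the group term) is refitted, residuals are resampled over
samples, and the maximum candidate-region area (sum of |delta beta| over
member probes) under the null is compared with each observed region's area
over B iterations, fwer = (#{max null area >= observed} + 1) / (B + 1).

No smoothing is applied to the per-probe effects before region finding: the
planted-region effects are locally constant and the 10% cutoff acts on the
raw beta differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import BetaMatrix, chrom_sort_key
from .qc_preprocess import beta_to_m, m_to_beta

__all__ = [
    "MAX_GAP",
    "ProbeCluster",
    "cluster_probes",
    "find_candidate_regions",
    "bootstrap_fwer",
    "annotate_dmrs",
]

MAX_GAP = 500  # bp; a gap of exactly 500 stays within the cluster

DMR_COLUMNS = [
    "chrom",
    "start",
    "end",
    "width",
    "probe_count",
    "mean_diff",
    "area",
    "fwer",
]


@dataclass
class ProbeCluster:
    chrom: str
    probe_ids: list
    positions: np.ndarray
    indices: np.ndarray  # row indices into the manifest used for clustering

    def __len__(self) -> int:
        return len(self.probe_ids)


def _cluster_ids(manifest: pd.DataFrame, max_gap: int) -> np.ndarray:
    """Per-row cluster id for a (chrom, pos)-sorted manifest."""
    chrom = manifest["chrom"].to_numpy()
    pos = manifest["pos"].to_numpy()
    new = np.ones(len(manifest), dtype=bool)
    if len(manifest) > 1:
        same_chrom = chrom[1:] == chrom[:-1]
        close = (pos[1:] - pos[:-1]) <= max_gap
        new[1:] = ~(same_chrom & close)
    return np.cumsum(new) - 1


def cluster_probes(manifest: pd.DataFrame, max_gap: int = MAX_GAP) -> list:
    """Greedy left-to-right clustering of probes per chromosome.

    The manifest must be sorted by (chrom, pos); a new cluster opens whenever
    the gap to the previous probe exceeds ``max_gap`` (a gap of exactly
    ``max_gap`` stays in the cluster).
    """
    ids = _cluster_ids(manifest, max_gap)
    clusters = []
    for cid in np.unique(ids):
        rows = np.flatnonzero(ids == cid)
        clusters.append(
            ProbeCluster(
                chrom=str(manifest["chrom"].iloc[rows[0]]),
                probe_ids=manifest["probe_id"].iloc[rows].tolist(),
                positions=manifest["pos"].iloc[rows].to_numpy(),
                indices=rows,
            )
        )
    return clusters


def _segment_regions(
    delta: np.ndarray,
    cluster_ids: np.ndarray,
    effect_cut: float,
    min_probes: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Maximal same-sign supra-threshold runs within clusters (vectorized).

    Returns (start_row, end_row_inclusive, mean_diff, area) arrays for runs
    with at least ``min_probes`` probes.
    """
    ok = np.abs(delta) > effect_cut
    if not ok.any():
        empty = np.empty(0)
        return empty.astype(int), empty.astype(int), empty, empty
    sgn = np.sign(delta)
    brk = np.ones(len(delta), dtype=bool)
    brk[1:] = (
        (cluster_ids[1:] != cluster_ids[:-1])
        | (sgn[1:] != sgn[:-1])
        | ~ok[:-1]
        | ~ok[1:]
    )
    # run starts: supra-threshold probes at a break point
    seg_start = np.flatnonzero(ok & brk)
    # a run extends while brk is False
    nxt_break = np.flatnonzero(brk)
    seg_end = np.empty_like(seg_start)
    for i, s in enumerate(seg_start):  # few starts in practice; loop is cheap
        j = np.searchsorted(nxt_break, s, side="right")
        seg_end[i] = (nxt_break[j] - 1) if j < len(nxt_break) else len(delta) - 1
    lengths = seg_end - seg_start + 1
    keep = lengths >= min_probes
    seg_start, seg_end = seg_start[keep], seg_end[keep]
    csum = np.concatenate([[0.0], np.cumsum(np.abs(delta))])
    area = csum[seg_end + 1] - csum[seg_start]
    csum_s = np.concatenate([[0.0], np.cumsum(delta)])
    mean_diff = (csum_s[seg_end + 1] - csum_s[seg_start]) / (seg_end - seg_start + 1)
    return seg_start, seg_end, mean_diff, area


def find_candidate_regions(
    delta_beta: pd.Series,
    manifest: pd.DataFrame,
    effect_cut: float = 0.10,
    min_probes: int = 3,
    max_gap: int = MAX_GAP,
) -> pd.DataFrame:
    """Candidate DMRs: same-sign runs of >=3 probes with |delta beta| > 10%.

    ``delta_beta`` must be indexed by probe id and cover the manifest.
    Region start/end are the min/max member positions (1-based inclusive).
    """
    delta = delta_beta.reindex(manifest["probe_id"]).to_numpy()
    if np.isnan(delta).any():
        raise ValueError("delta_beta does not cover every manifest probe")
    ids = _cluster_ids(manifest, max_gap)
    s, e, mean_diff, area = _segment_regions(delta, ids, effect_cut, min_probes)
    pos = manifest["pos"].to_numpy()
    rows = []
    for i in range(len(s)):
        member = slice(s[i], e[i] + 1)
        rows.append(
            {
                "chrom": manifest["chrom"].iloc[s[i]],
                "start": int(pos[member].min()),
                "end": int(pos[member].max()),
                "width": int(pos[member].max() - pos[member].min() + 1),
                "probe_count": int(e[i] - s[i] + 1),
                "mean_diff": float(mean_diff[i]),
                "area": float(area[i]),
                "probe_ids": manifest["probe_id"].iloc[member].tolist(),
            }
        )
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "width", "probe_count", "mean_diff", "area", "probe_ids"])
    if len(out):
        out = out.sort_values(
            ["chrom", "start"], key=lambda c: c.map(chrom_sort_key) if c.name == "chrom" else c
        ).reset_index(drop=True)
    return out


def bootstrap_fwer(
    M: pd.DataFrame,
    design: pd.DataFrame,
    candidates: pd.DataFrame,
    manifest: pd.DataFrame,
    B: int = 1000,
    seed: int = 0,
    effect_cut: float = 0.10,
    min_probes: int = 3,
    delta_cut: float = 0.10,
    max_gap: int = MAX_GAP,
) -> pd.DataFrame:
    """Residual-bootstrap family-wise error rates for candidate regions.

    The null model is the design without its group column.  Residuals are
    taken from the full-model fit (so they are exchangeable under the null
    and carry no group effect), resampled over samples (one resample shared
    by all probes per iteration) and added to the null fitted values; each
    iteration recomputes beta-scale group differences, re-runs region
    finding, and records the maximum region area.  Retained rows satisfy
    fwer < 0.01, |mean_diff| > ``delta_cut`` and probe_count >=
    ``min_probes``.
    """
    if B < 100:
        warnings.warn(f"B = {B} gives poor FWER resolution; use B >= 100")
    if len(candidates) == 0:
        return pd.DataFrame(columns=DMR_COLUMNS + ["probe_ids"])

    rng = np.random.default_rng(seed)
    X0 = design.drop(columns="group")
    Xn = X0.to_numpy()
    M = M.reindex(manifest["probe_id"])
    if M.isna().any().any():
        raise ValueError("M matrix does not cover every manifest probe")
    Y = M[design.index].to_numpy()  # probes x n, manifest row order
    # null fitted values, but residuals from the full fit: under the null
    # both agree, and under the alternative the group effect must not leak
    # into the resampled noise
    Xf = design.to_numpy()
    beta_full = np.linalg.lstsq(Xf, Y.T, rcond=None)[0]
    resid = Y - (Xf @ beta_full).T
    beta_null = np.linalg.lstsq(Xn, Y.T, rcond=None)[0]
    fitted = (Xn @ beta_null).T

    grp = design["group"].to_numpy() == 1.0
    n = Y.shape[1]
    n_pat, n_ctl = int(grp.sum()), int((~grp).sum())
    cluster_ids = _cluster_ids(manifest, max_gap)

    max_areas = np.zeros(B)
    for b in range(B):
        take = rng.integers(0, n, size=n)
        Mb = fitted + resid[:, take]
        bb = m_to_beta(Mb)
        db = bb[:, grp].sum(axis=1) / n_pat - bb[:, ~grp].sum(axis=1) / n_ctl
        s, e, _, area = _segment_regions(db, cluster_ids, effect_cut, min_probes)
        if len(area):
            max_areas[b] = area.max()

    obs_area = candidates["area"].to_numpy()
    exceed = (max_areas[None, :] >= obs_area[:, None]).sum(axis=1)
    fwer = (exceed + 1.0) / (B + 1.0)
    out = candidates.copy()
    out["fwer"] = fwer
    keep = (
        (out["fwer"] < 0.01)
        & (out["mean_diff"].abs() > delta_cut)
        & (out["probe_count"] >= min_probes)
    )
    out = out.loc[keep, ["chrom", "start", "end", "width", "probe_count", "mean_diff", "area", "fwer", "probe_ids"]]
    return out.sort_values("area", ascending=False).reset_index(drop=True)


def _read_gene_bed(path) -> pd.DataFrame:
    rows = []
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed BED line {line_no}: {line!r}")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"malformed BED line {line_no}: {line!r}") from exc
            name = parts[3] if len(parts) > 3 else "."
            strand = parts[5] if len(parts) > 5 else "+"
            rows.append((parts[0], start, end, name, strand))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "strand"])


def annotate_dmrs(
    dmrs: pd.DataFrame,
    manifest: pd.DataFrame,
    gene_bed=None,
    tss_window: int = 2000,
) -> pd.DataFrame:
    """Attach gene overlap and CpG-island distance annotations.

    ``overlapping_gene`` is the name of any gene interval (0-based half-open
    BED) intersecting the region, or, failing that, a gene whose TSS lies
    within ``tss_window`` bp downstream of the region (distance reported in
    parentheses).  ``dist_to_island`` is 0 when a member probe is annotated
    as island, otherwise the distance to the nearest island probe on the
    same chromosome.
    """
    out = dmrs.copy()
    genes = _read_gene_bed(gene_bed) if gene_bed is not None else None
    island = manifest[manifest["island_relation"] == "island"]
    gene_col, dist_col = [], []
    for _, row in out.iterrows():
        # gene overlap: region is 1-based inclusive, BED half-open
        name = ""
        if genes is not None:
            g = genes[genes["chrom"] == row["chrom"]]
            hit = g[(g["start"] < row["end"]) & (g["end"] > row["start"] - 1)]
            if len(hit):
                name = str(hit.iloc[0]["name"])
            else:
                for _, gr in g.iterrows():
                    tss = gr["start"] + 1 if gr["strand"] != "-" else gr["end"]
                    dist = tss - row["end"] if gr["strand"] != "-" else row["start"] - tss
                    if 0 < dist <= tss_window:
                        name = f"{gr['name']} ({int(dist)})"
                        break
        gene_col.append(name)

        members = set(row["probe_ids"]) if "probe_ids" in row else set()
        member_rows = manifest[manifest["probe_id"].isin(members)]
        if (member_rows["island_relation"] == "island").any():
            dist_col.append(0)
        else:
            isl = island[island["chrom"] == row["chrom"]]
            if len(isl) == 0:
                dist_col.append(np.nan)
            else:
                pos = member_rows["pos"].to_numpy()[:, None]
                dist_col.append(int(np.abs(pos - isl["pos"].to_numpy()[None, :]).min()))
    out["overlapping_gene"] = gene_col
    out["dist_to_island"] = dist_col
    return out
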
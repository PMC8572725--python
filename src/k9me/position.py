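"""Subnuclear positioning: DamID bin log-ratios and 3D focus imaging.

DamID lamina association is measured per 10-kb genomic bin as the log2
ratio of library-scaled nuclear-envelope-fusion (EMR-1::Dam) counts over
the free-Dam control, pseudo-count 8 on both sides, and compared across
gene groups with a two-sided Wilcoxon rank-sum test.

Imaging follows the focus-positioning quantification: nuclei are
segmented by seeded watershed on the envelope channel, foci are detected
by a Laplacian-of-Gaussian filter on the focus channel, and each focus's
distance to the nuclear periphery is read off a 3D Euclidean distance
transform of the nucleus mask (anisotropic voxel spacing honoured).
Foci outside every nucleus are excluded.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import regionprops
from skimage.segmentation import watershed

from k9me.chic import WindowTrack
from k9me.genomic_io import GeneModel


# --------------------------------------------------------------------------
# DamID


def damid_bin_ratio(
    fusion: WindowTrack,
    control: WindowTrack,
    pseudo: float = 8.0,
) -> WindowTrack:
    """Per-bin log2((scaled fusion + 8) / (scaled control + 8)).

    Both tracks are library-scaled to their mean total first. Bin width
    is whatever the tracks carry (10 kb in the study).
    """
    if not fusion.same_tiling(control):
        raise ValueError("fusion/control tiling mismatch")
    totals = np.array([fusion.total, control.total])
    if np.any(totals == 0):
        raise ValueError("zero-total DamID track")
    mean_total = totals.mean()
    values = {}
    for chrom in fusion.chrom_lengths:
        f = fusion.values[chrom] * (mean_total / totals[0])
        c = control.values[chrom] * (mean_total / totals[1])
        values[chrom] = np.log2((f + pseudo) / (c + pseudo))
    return WindowTrack(
        width=fusion.width, chrom_lengths=fusion.chrom_lengths, values=values
    )


def gene_bin_values(
    track: WindowTrack, genes: Sequence[GeneModel]
) -> dict[str, np.ndarray]:
    """Per-gene vector of bin values for every bin the gene span overlaps
    (each overlapped bin contributes once)."""
    w = track.width
    out = {}
    for g in genes:
        L = track.chrom_lengths[g.chrom]
        span = g.span
        first = span.start // w
        last = min(span.end - 1, L - 1) // w
        out[g.gene_id] = track.values[g.chrom][first : last + 1]
    return out


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact by full enumeration of rank assignments when the combined
    sample size is <= 12 and there are no ties; otherwise the
    tie-corrected normal approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("rank_sum_test requires non-empty samples")
    combined = np.concatenate([x, y])
    no_ties = len(np.unique(combined)) == combined.size
    if combined.size <= 12 and no_ties:
        return _rank_sum_exact(x, y)
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return float(res.pvalue)


def _rank_sum_exact(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided p by enumerating which ranks belong to x: the
    p-value is the fraction of assignments whose rank sum deviates from
    its mean by at least as much as the observed one."""
    n, m = len(x), len(y)
    ranks = stats.rankdata(np.concatenate([x, y]))
    w_obs = ranks[:n].sum()
    mu = n * (n + m + 1) / 2.0
    dev = abs(w_obs - mu)
    total = 0
    extreme = 0
    all_ranks = np.arange(1, n + m + 1)
    for combo in itertools.combinations(all_ranks, n):
        total += 1
        if abs(sum(combo) - mu) >= dev - 1e-12:
            extreme += 1
    return extreme / total


def group_position_compare(
    track: WindowTrack,
    groups: pd.DataFrame | Mapping[str, str],
    genes: Sequence[GeneModel],
    which: Sequence[str] = ("A", "B", "C"),
    min_group_size: int = 2,
) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Pool DamID bin values per gene group and compare groups pairwise.

    Returns (per-group value vectors, long-format table of pairwise
    two-sided rank-sum p-values). Groups with fewer than
    ``min_group_size`` genes are skipped.
    """
    labels = groups["group"] if isinstance(groups, pd.DataFrame) else pd.Series(groups)
    per_gene = gene_bin_values(track, genes)
    pooled: dict[str, np.ndarray] = {}
    for grp in which:
        gids = [g.gene_id for g in genes if labels.get(g.gene_id) == grp]
        if len(gids) < min_group_size:
            continue
        pooled[grp] = np.concatenate([per_gene[g] for g in gids])
    rows = []
    for g1, g2 in itertools.combinations(sorted(pooled), 2):
        rows.append(
            {
                "group_1": g1,
                "group_2": g2,
                "n_1": len(pooled[g1]),
                "n_2": len(pooled[g2]),
                "pvalue": rank_sum_test(pooled[g1], pooled[g2]),
            }
        )
    return pooled, pd.DataFrame(rows)


# --------------------------------------------------------------------------
# 3D imaging


@dataclass
class FocusRecord:
    """A detected focus with its nucleus assignment and periphery distance.

    Coordinates and distances are in physical units (e.g. micrometres);
    ``excluded`` marks foci that fall outside every nucleus mask.
    """

    z: float
    y: float
    x: float
    intensity: float
    diameter: float
    nucleus_label: int
    distance_to_periphery: float
    excluded: bool


def segment_nuclei(
    channel: np.ndarray,
    voxel_size: tuple[float, float, float],
    smooth_sigma: float = 0.3,
    min_volume: float = 1.0,
) -> np.ndarray:
    """Seeded-watershed segmentation of nuclei on the envelope channel.

    The channel is Gaussian-smoothed (``smooth_sigma`` in physical
    units), thresholded with Otsu, seeded at local maxima of the
    smoothed image, and flooded by watershed on the inverted smoothed
    intensity inside the foreground. Labels smaller than ``min_volume``
    (physical units cubed) are dropped. A blank channel yields an empty
    label image.
    """
    vz, vy, vx = voxel_size
    if min(voxel_size) <= 0:
        raise ValueError("voxel sizes must be positive")
    img = channel.astype(float)
    if img.max() <= img.min():
        return np.zeros(channel.shape, dtype=np.int32)
    sigma_vox = (smooth_sigma / vz, smooth_sigma / vy, smooth_sigma / vx)
    smoothed = gaussian(img, sigma=sigma_vox, preserve_range=True)
    thresh = threshold_otsu(smoothed)
    foreground = smoothed > thresh
    if not foreground.any():
        return np.zeros(channel.shape, dtype=np.int32)
    # seeds: well-separated maxima of the smoothed signal inside the mask
    min_dist_vox = max(1, int(round(1.0 / min(voxel_size))))
    coords = peak_local_max(
        smoothed, labels=foreground, min_distance=min_dist_vox, exclude_border=False
    )
    markers = np.zeros(channel.shape, dtype=np.int32)
    for i, c in enumerate(coords, start=1):
        markers[tuple(c)] = i
    if markers.max() == 0:
        markers[np.unravel_index(np.argmax(smoothed), smoothed.shape)] = 1
    labels = watershed(-smoothed, markers=markers, mask=foreground)
    voxel_vol = vz * vy * vx
    out = np.zeros_like(labels, dtype=np.int32)
    next_label = 1
    for prop in regionprops(labels):
        if prop.num_pixels * voxel_vol >= min_volume:
            out[labels == prop.label] = next_label
            next_label += 1
    return out


def detect_foci(
    channel: np.ndarray,
    voxel_size: tuple[float, float, float],
    sigma: float = 0.15,
    quality_min: float | None = None,
) -> list[tuple[int, int, int, float]]:
    """Laplacian-of-Gaussian focus detection.

    ``sigma`` is the expected focus radius scale in physical units;
    per-axis voxel sigmas honour anisotropy. Returns (z, y, x, response)
    voxel coordinates of LoG response maxima above ``quality_min``; the
    centre is the maximal voxel (no subvoxel fit). When ``quality_min``
    is None the threshold is set from the response's own noise floor
    (median + 8 robust standard deviations), so a blank channel yields
    no foci.
    """
    vz, vy, vx = voxel_size
    sigma_vox = (sigma / vz, sigma / vy, sigma / vx)
    # scale-normalized negated LoG: bright blobs -> positive response
    response = -ndimage.gaussian_laplace(channel.astype(float), sigma=sigma_vox)
    response *= sigma**2
    if quality_min is None:
        mad = np.median(np.abs(response - np.median(response)))
        quality_min = float(np.median(response) + 8 * 1.4826 * mad)
        if quality_min <= 0:
            quality_min = np.finfo(float).tiny
    min_dist = max(1, int(round(2 * min(sigma_vox))))
    coords = peak_local_max(
        response,
        min_distance=min_dist,
        threshold_abs=quality_min,
        exclude_border=False,
    )
    # plateau peaks (exactly equal responses) all survive peak_local_max;
    # greedily keep the strongest representative per 2-sigma neighbourhood
    spacing = np.array(voxel_size)
    order = np.argsort([-response[tuple(c)] for c in coords], kind="stable")
    kept: list[np.ndarray] = []
    for i in order:
        c = coords[i]
        pos_phys = c * spacing
        if all(
            np.linalg.norm(pos_phys - k * spacing) > 2 * sigma for k in kept
        ):
            kept.append(c)
    kept.sort(key=lambda c: tuple(c))
    return [
        (int(z), int(y), int(x), float(response[z, y, x])) for z, y, x in kept
    ]


def periphery_distance_map(
    masks: np.ndarray, voxel_size: tuple[float, float, float]
) -> np.ndarray:
    """Exact Euclidean distance transform of the (union) nucleus mask:
    per-voxel distance to the nearest background voxel, in physical
    units, anisotropic spacing honoured."""
    return ndimage.distance_transform_edt(masks > 0, sampling=voxel_size)


def focus_periphery_distance(
    masks: np.ndarray,
    foci: Sequence[tuple[int, int, int, float]],
    voxel_size: tuple[float, float, float],
    channel: np.ndarray | None = None,
    sigma: float = 0.15,
) -> list[FocusRecord]:
    """Measure each focus's distance to the nuclear periphery.

    The distance is the value of the Euclidean distance transform at the
    focus voxel; foci on background (outside every nucleus) are flagged
    excluded with distance NaN. Focus diameter is reported from the
    detection scale (2*sqrt(3)*sigma, the LoG blob convention).
    """
    vz, vy, vx = voxel_size
    edt = periphery_distance_map(masks, voxel_size)
    records = []
    for z, y, x, response in foci:
        label = int(masks[z, y, x])
        inside = label > 0
        intensity = float(channel[z, y, x]) if channel is not None else response
        records.append(
            FocusRecord(
                z=z * vz,
                y=y * vy,
                x=x * vx,
                intensity=intensity,
                diameter=2.0 * np.sqrt(3.0) * sigma,
                nucleus_label=label,
                distance_to_periphery=float(edt[z, y, x]) if inside else float("nan"),
                excluded=not inside,
            )
        )
    return records


def focus_records_to_frame(records: Sequence[FocusRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "nucleus_label": [r.nucleus_label for r in records],
            "z": [r.z for r in records],
            "y": [r.y for r in records],
            "x": [r.x for r in records],
            "intensity": [r.intensity for r in records],
            "diameter": [r.diameter for r in records],
            "distance": [r.distance_to_periphery for r in records],
            "excluded": [r.excluded for r in records],
        }
    )
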
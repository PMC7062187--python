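"""Synthetic screens, expression matrices and time-lapse stacks with
planted ground truth.

The original screen's raw well data are not publicly deposited, so every
downstream stage is exercised on generated data that reproduces the
statistical structure the real analysis faced:

* correlated blocks among the 84 well-summary parameters (shared latent
  factor per block);
* an informative subset of parameters (65 by default) that respond to
  recruitment modulation with a common sign — higher value = more
  recruitment — while the rest never respond;
* negative controls at baseline, positive controls (PINK1 knockdown)
  suppressed by a large margin on the informative parameters;
* planted positive modulators (knockdown suppresses recruitment, effect
  direction -1) and negative modulators (+1);
* per-plate linear row/column gradients and degraded "bad" plates whose
  control separation collapses;
* a bimodal expressed/non-expressed log-intensity mixture for the
  expression gate;
* two-channel time-lapse frames with elliptical nuclei and Gaussian-spot
  puncta whose per-cell counts peak in an assigned 2-hour window.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections.abc import Sequence

import numpy as np
import pandas as pd

from .errors import CapacityError, PlacementError
from .screen import (
    ROLE_EMPTY,
    ROLE_NEGATIVE,
    ROLE_POSITIVE,
    ROLE_SAMPLE,
    ScreenDataset,
    default_parameter_names,
    get_layout,
    well_to_rc,
)
from .timelapse import WINDOWS, CellTrack, TimelapseStack, peak_window


@dataclasses.dataclass
class ScreenSimConfig:
    """Study conditions for a synthetic plate screen.

    Effects and separations are expressed in units of the replicate noise
    S.D.  Defaults emulate a primary screen: 3 replicates, strong positive
    controls, planted modulators at a 4-S.D. knockdown effect.
    """

    n_plates: int = 4
    replicates: int = 3
    layout_name: str = "primary"
    n_parameters: int = 84
    informative_parameter_count: int = 65
    planted_positive_modulators: Sequence[str] = ()
    planted_negative_modulators: Sequence[str] = ()
    effect_size_sd_units: float = 4.0
    control_separation_sd_units: float = 6.0
    row_slope: float = 0.0
    col_slope: float = 0.0
    bad_plate_ids: Sequence[str] = ()
    noise_sd: float = 1.0
    correlation_block_size: int = 7
    # within-block correlation; calibrated so the default screen's PCA
    # consensus score keeps its ~1% null tail at the +-3 threshold (the
    # first component inflates correlated SSMD noise by up to sqrt(3))
    block_correlation: float = 0.4
    sirnas_per_gene: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        overlap = set(self.planted_positive_modulators) & set(self.planted_negative_modulators)
        if overlap:
            raise ValueError(f"planted gene lists must be disjoint, overlap: {sorted(overlap)}")
        if self.informative_parameter_count > self.n_parameters:
            raise ValueError("informative_parameter_count must be <= n_parameters")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")


@dataclasses.dataclass
class GroundTruth:
    """What the generator planted: per-gene direction, gradients, informative set."""

    direction: dict[str, int]  # gene_id -> -1 / 0 / +1
    plate_slopes: dict[str, tuple[float, float]]  # plate_id -> (row, col)
    informative: dict[str, bool]  # parameter -> responds to modulation

    def planted_genes(self) -> list[str]:
        return sorted(g for g, d in self.direction.items() if d != 0)


def _correlated_noise(rng: np.random.Generator, n_wells: int, n_params: int,
                      block_size: int, rho: float, sd: float) -> np.ndarray:
    """Block-correlated Gaussian noise: one shared latent factor per block."""
    eps = rng.standard_normal((n_wells, n_params))
    if rho > 0 and block_size > 1:
        n_blocks = int(np.ceil(n_params / block_size))
        latent = rng.standard_normal((n_wells, n_blocks))
        block_of = np.arange(n_params) // block_size
        eps = np.sqrt(rho) * latent[:, block_of] + np.sqrt(1.0 - rho) * eps
    return sd * eps


def simulate_screen(config: ScreenSimConfig) -> tuple[ScreenDataset, GroundTruth]:
    """Generate a screen and its ground truth, reproducibly from the seed."""
    rng = np.random.default_rng(config.seed)
    layout = get_layout(config.layout_name)
    params = default_parameter_names(config.n_parameters)
    informative = {p: i < config.informative_parameter_count for i, p in enumerate(params)}
    info_mask = np.array([informative[p] for p in params])

    sample_wells = layout.wells_of_role(ROLE_SAMPLE)
    n_genes = config.n_plates * len(sample_wells) // max(1, config.sirnas_per_gene)
    planted = list(config.planted_positive_modulators) + list(config.planted_negative_modulators)
    if len(planted) > n_genes:
        raise CapacityError(
            f"{len(planted)} planted genes exceed the {n_genes} sample slots available"
        )
    gene_ids = [f"G{i + 1:05d}" for i in range(n_genes - len(planted))]
    gene_ids = list(planted) + gene_ids
    # plant modulators at random positions so they never align with plates
    order = rng.permutation(len(gene_ids))
    gene_ids = [gene_ids[i] for i in order]
    direction = {g: 0 for g in gene_ids}
    for g in config.planted_positive_modulators:
        direction[g] = -1  # knockdown of a positive modulator suppresses recruitment
    for g in config.planted_negative_modulators:
        direction[g] = +1

    sigma = config.noise_sd
    effect = config.effect_size_sd_units * sigma
    separation = config.control_separation_sd_units * sigma

    records = []
    shifts = []
    plate_slopes: dict[str, tuple[float, float]] = {}
    gene_cursor = 0
    sirna_cycle = 0
    # assign genes/siRNAs to wells once; replicates repeat the assignment
    assignments: dict[str, list[tuple[str, str | None, str | None]]] = {}
    for p in range(config.n_plates):
        plate_id = f"P{p + 1:03d}"
        plate_slopes[plate_id] = (config.row_slope, config.col_slope)
        plate_assign = []
        for well in sorted(layout.role_map, key=well_to_rc):
            role = layout.role_map[well]
            if role == ROLE_SAMPLE:
                gene = gene_ids[gene_cursor]
                sirna = f"{gene}_s{sirna_cycle + 1}"
                plate_assign.append((well, gene, sirna))
                sirna_cycle += 1
                if sirna_cycle >= config.sirnas_per_gene:
                    sirna_cycle = 0
                    gene_cursor += 1
                    if gene_cursor >= len(gene_ids):
                        gene_cursor = 0  # wrap only if capacity math left slack
            else:
                plate_assign.append((well, None, None))
        assignments[plate_id] = plate_assign

    for plate_id, plate_assign in assignments.items():
        bad = plate_id in set(config.bad_plate_ids)
        sep = 0.0 if bad else separation
        for rep in range(1, config.replicates + 1):
            for well, gene, sirna in plate_assign:
                role = layout.role_map[well]
                row, col = well_to_rc(well)
                shift = np.zeros(len(params))
                if role == ROLE_POSITIVE:
                    shift[info_mask] = -sep
                elif role == ROLE_SAMPLE and direction[gene] != 0:
                    shift[info_mask] = direction[gene] * effect
                gradient = config.row_slope * row + config.col_slope * col
                shifts.append(shift + gradient)
                records.append(
                    {
                        "plate_id": plate_id,
                        "replicate": rep,
                        "well": well,
                        "role": role,
                        "gene_id": gene,
                        "sirna_id": sirna,
                    }
                )
    meta = pd.DataFrame(records)
    noise = _correlated_noise(
        rng, len(meta), len(params), config.correlation_block_size,
        config.block_correlation, sigma,
    )
    values = np.asarray(shifts) + noise
    wells = pd.concat([meta, pd.DataFrame(values, columns=params)], axis=1)
    dataset = ScreenDataset(layout, params, wells)
    truth = GroundTruth(direction=direction, plate_slopes=plate_slopes, informative=informative)
    return dataset, truth


def simulate_expression(
    n_genes: int,
    expressed_fraction: float = 0.5,
    mu_off: float = 4.0,
    mu_on: float = 9.0,
    sigma_off: float = 1.0,
    sigma_on: float = 1.0,
    n_samples: int = 11,
    sample_noise_sd: float = 3.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, set[str]]:
    """Bimodal log-intensity matrix: per-gene mean from a two-Gaussian
    mixture, per-sample values = gene mean + Gaussian noise.

    ``n_samples`` defaults to 11, matching the 8 + 3 public-array design
    the expression gate was built for.  Those samples pool several
    platforms and laboratories, so the default per-sample noise is large
    relative to the component widths (between-study scatter dominates
    between-gene scatter within a component).  Returns the matrix and the
    set of genes drawn from the expressed (higher-mean) component.
    """
    if not 0 <= expressed_fraction <= 1:
        raise ValueError("expressed_fraction must be in [0, 1]")
    if sigma_off <= 0 or sigma_on <= 0:
        raise ValueError("component sigmas must be > 0")
    if mu_on == mu_off:
        warnings.warn("mu_on == mu_off: generating a unimodal (degenerate) matrix")
    elif mu_on < mu_off:
        raise ValueError("mu_on must be >= mu_off")
    rng = np.random.default_rng(seed)
    genes = [f"G{i + 1:05d}" for i in range(n_genes)]
    expressed = rng.random(n_genes) < expressed_fraction
    means = np.where(
        expressed,
        rng.normal(mu_on, sigma_on, n_genes),
        rng.normal(mu_off, sigma_off, n_genes),
    )
    values = means[:, None] + rng.normal(0.0, sample_noise_sd, (n_genes, n_samples))
    matrix = pd.DataFrame(
        values, index=genes, columns=[f"S{j + 1:02d}" for j in range(n_samples)]
    )
    return matrix, {g for g, e in zip(genes, expressed) if e}


# ---------------------------------------------------------------------------
# time-lapse rendering


def _place_nuclei(rng, n_cells, shape, radius, min_sep, max_tries=2000):
    centers = []
    h, w = shape
    margin = 3 * radius
    for _ in range(n_cells):
        for _try in range(max_tries):
            c = (rng.uniform(margin, h - margin), rng.uniform(margin, w - margin))
            if all(np.hypot(c[0] - y, c[1] - x) >= min_sep for y, x in centers):
                centers.append(c)
                break
        else:
            raise PlacementError(
                f"could not place {n_cells} non-overlapping nuclei on a {shape} frame"
            )
    return centers


def _count_trajectory(rng, n_frames, interval_min, window: str, baseline=1, peak=7):
    """Integer puncta counts ramping to a peak inside the assigned window."""
    lo, hi = {"h0_2": (0, 120), "h2_4": (120, 240), "h4_6": (240, 360)}[window]
    frames_in = [t for t in range(n_frames) if lo < t * interval_min <= hi or
                 (window == "h0_2" and t == 0)]
    peak_frame = int(rng.choice(frames_in[1:-1] if len(frames_in) > 2 else frames_in))
    counts = np.full(n_frames, baseline, dtype=int)
    rise = max(1, peak_frame)
    for t in range(n_frames):
        if t <= peak_frame:
            counts[t] = round(baseline + (peak - baseline) * (t / rise) ** 2)
        else:
            counts[t] = max(baseline, round(peak - 0.6 * (t - peak_frame)))
    counts[peak_frame] = peak
    # keep the global maximum unique and inside the window
    counts[np.arange(n_frames) != peak_frame] = np.minimum(
        counts[np.arange(n_frames) != peak_frame], peak - 1
    )
    return counts, peak_frame


def _render_spots(img, rng, center, diameter, n_spots, amplitude, spot_sigma, min_sep):
    placed = []
    cy, cx = center
    rmax = 0.8 * diameter
    h, w = img.shape
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(n_spots):
        for _try in range(500):
            ang = rng.uniform(0, 2 * np.pi)
            r = rng.uniform(0.15 * diameter, rmax)
            py, px = cy + r * np.sin(ang), cx + r * np.cos(ang)
            if not (0 < py < h and 0 < px < w):
                continue
            if all(np.hypot(py - y, px - x) >= min_sep for y, x in placed):
                placed.append((py, px))
                break
        else:  # pragma: no cover - generous capacity by construction
            raise PlacementError("could not place puncta without overlap")
        img += amplitude * np.exp(-((yy - py) ** 2 + (xx - px) ** 2) / (2 * spot_sigma**2))
    return placed


def simulate_timelapse(
    n_cells: int,
    frames: int = 25,
    interval_min: int = 15,
    peak_window_assignment: Sequence[str] | None = None,
    shape: tuple[int, int] = (256, 256),
    nucleus_radius: float = 9.0,
    puncta_amplitude: float = 120.0,
    puncta_sigma: float = 2.0,
    noise_sd: float = 2.0,
    seed: int = 0,
) -> tuple[TimelapseStack, list[CellTrack]]:
    """Render a two-channel stack with known per-cell puncta trajectories.

    Nuclei are static ellipses (small per-frame jitter); puncta are
    Gaussian spots near their nucleus whose per-frame count follows a
    planted trajectory peaking inside the assigned window.  Returns the
    stack and the true tracks.
    """
    if (frames - 1) * interval_min < 360:
        raise ValueError("frames * interval must span the full 6-hour grouping range")
    rng = np.random.default_rng(seed)
    if peak_window_assignment is None:
        peak_window_assignment = [WINDOWS[i % 3] for i in range(n_cells)]
    if len(peak_window_assignment) != n_cells:
        raise ValueError("peak_window_assignment must have one window per cell")

    h, w = shape
    stack = np.zeros((frames, 2, h, w), dtype=float)
    if n_cells == 0:
        stack += rng.normal(5.0, noise_sd, stack.shape)
        return TimelapseStack(np.clip(stack, 0, None), interval_min), []

    diameter = 2 * nucleus_radius
    centers = _place_nuclei(rng, n_cells, shape, nucleus_radius, min_sep=2.6 * diameter)
    axes = [(nucleus_radius * rng.uniform(1.0, 1.15), nucleus_radius * rng.uniform(0.8, 0.95))
            for _ in range(n_cells)]
    trajectories = []
    for i in range(n_cells):
        counts, peak_frame = _count_trajectory(rng, frames, interval_min, peak_window_assignment[i])
        trajectories.append(counts)

    yy, xx = np.mgrid[0:h, 0:w]
    tracks: list[CellTrack] = []
    cell_centroids: list[list[tuple[float, float]]] = [[] for _ in range(n_cells)]
    for t in range(frames):
        nuc = np.full((h, w), 5.0)
        rep = np.full((h, w), 8.0)
        for i, (cy0, cx0) in enumerate(centers):
            cy = cy0 + rng.normal(0, 0.5)
            cx = cx0 + rng.normal(0, 0.5)
            a, b = axes[i]
            ellipse = ((yy - cy) / a) ** 2 + ((xx - cx) / b) ** 2 <= 1.0
            nuc[ellipse] = np.maximum(nuc[ellipse], 100.0)
            cell_centroids[i].append((cy, cx))
            _render_spots(
                rep, rng, (cy, cx), diameter, int(trajectories[i][t]),
                puncta_amplitude, puncta_sigma, min_sep=4.0 * puncta_sigma,
            )
        nuc += rng.normal(0, noise_sd, (h, w))
        rep += rng.normal(0, noise_sd, (h, w))
        stack[t, 0] = np.clip(nuc, 0, None)
        stack[t, 1] = np.clip(rep, 0, None)

    for i in range(n_cells):
        tracks.append(
            CellTrack(
                cell_id=i,
                centroids=cell_centroids[i],
                diameters=[2 * axes[i][0]] * frames,
                counts=[int(c) for c in trajectories[i]],
                interval_min=interval_min,
            )
        )
        assert tracks[-1].peak_window == peak_window_assignment[i], (
            "planted trajectory must peak in its assigned window"
        )
    return TimelapseStack(stack, interval_min), tracks
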
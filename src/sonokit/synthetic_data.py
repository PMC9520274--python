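"""Synthetic inputs for the quantification pipeline.

Two generators: (a) replicate-level experiment tables drawn from the
shipped registry of published group summaries (truncated-normal noise
around each group's mean/sd, bounded to [0, 100] %), and (b) two-channel
microscopy frames of disk-shaped cells with exact ground truth, for
validating the counting pipeline.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import yaml
from scipy import stats as sps

from .image_quant import TwoChannelFrame
from .uptake_stats import ExperimentTable, GroupMeasurements

__all__ = [
    "GroupSpec",
    "ImageSpec",
    "FrameTruth",
    "load_registry",
    "registry_lookup",
    "synth_replicates",
    "synth_experiment",
    "synth_frame",
    "PlacementError",
]

PERCENT_BOUNDS = (0.0, 100.0)


@dataclass(frozen=True)
class GroupSpec:
    """Target summary statistics for one synthetic group."""

    group_label: str
    target_mean: float  # %
    target_sd: float  # %
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if not PERCENT_BOUNDS[0] <= self.target_mean <= PERCENT_BOUNDS[1]:
            raise ValueError("target_mean must be in [0, 100]")
        if self.target_sd < 0:
            raise ValueError("target_sd must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass(frozen=True)
class ImageSpec:
    """Layout of a synthetic two-channel frame: ``n_cells`` non-overlapping
    disks in the nuclear channel, of which round(stained_fraction * n_cells)
    are also painted in the reporter channel."""

    width: int = 256
    height: int = 256
    n_cells: int = 100
    stained_fraction: float = 0.3
    disk_radius: int = 6
    nuclear_intensity: int = 30000
    reporter_intensity: int = 30000
    background: int = 200
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if not 0.0 <= self.stained_fraction <= 1.0:
            raise ValueError("stained_fraction must be in [0, 1]")
        if self.disk_radius < 1:
            raise ValueError("disk_radius must be >= 1")
        if 2 * self.disk_radius + 2 >= min(self.width, self.height):
            raise ValueError("disks do not fit in the frame")


@dataclass(frozen=True)
class FrameTruth:
    """Ground truth accompanying a synthetic frame."""

    n_cells: int
    n_stained: int
    centroids_xy: tuple[tuple[float, float], ...]
    stained_flags: tuple[bool, ...]


class PlacementError(RuntimeError):
    """Non-overlapping disk placement failed; use fewer or smaller disks."""


# ---------------------------------------------------------------------------
# Registry of published group summaries


def load_registry() -> list[dict]:
    """The shipped read-only registry of published per-group summaries."""
    text = resources.files("sonokit.data").joinpath("group_summaries.yaml").read_text()
    return yaml.safe_load(text)


def registry_lookup(
    molecule: str, metric: str, timepoint_h: float, registry: Optional[list[dict]] = None
) -> dict[str, tuple[float, float]]:
    """Map group label -> (mean, sd) for one experiment, or raise KeyError
    naming the missing key."""
    registry = load_registry() if registry is None else registry
    for entry in registry:
        if (
            entry["molecule"] == molecule
            and entry["metric"] == metric
            and float(entry["timepoint_h"]) == float(timepoint_h)
        ):
            return {
                label: (float(v["mean"]), float(v["sd"]))
                for label, v in entry["groups"].items()
            }
    raise KeyError(
        f"no registry entry for (molecule={molecule!r}, metric={metric!r}, "
        f"timepoint_h={timepoint_h!r})"
    )


# ---------------------------------------------------------------------------
# Replicate tables


def synth_replicates(spec: GroupSpec, seed: int) -> GroupMeasurements:
    """Draw replicate values from a normal(target_mean, target_sd)
    truncated to [0, 100]; sd = 0 degenerates to exact repetition."""
    if spec.target_sd == 0.0:
        values = np.full(spec.n_replicates, spec.target_mean)
    else:
        lo, hi = PERCENT_BOUNDS
        a = (lo - spec.target_mean) / spec.target_sd
        b = (hi - spec.target_mean) / spec.target_sd
        rng = np.random.default_rng(seed)
        values = sps.truncnorm.rvs(
            a, b, loc=spec.target_mean, scale=spec.target_sd,
            size=spec.n_replicates, random_state=rng,
        )
    return GroupMeasurements(group_label=spec.group_label, replicate_values=values)


def synth_experiment(
    molecule: str,
    metric: str,
    timepoint_h: float,
    seed: int,
    n_replicates: int = 3,
    zero_sd: bool = False,
    registry: Optional[list[dict]] = None,
) -> ExperimentTable:
    """Synthesize a full experiment table from the registry.

    ``zero_sd`` replaces every group's sd with 0, making the table carry
    the registry means exactly (useful for deterministic downstream
    arithmetic). Group-level seeds are derived from ``seed`` so tables are
    reproducible and groups independent.
    """
    summary = registry_lookup(molecule, metric, timepoint_h, registry)
    seed_seq = np.random.SeedSequence(seed)
    child_seeds = seed_seq.spawn(len(summary))
    groups = []
    for (label, (mean, sd)), child in zip(summary.items(), child_seeds):
        spec = GroupSpec(
            group_label=label,
            target_mean=mean,
            target_sd=0.0 if zero_sd else sd,
            n_replicates=n_replicates,
        )
        groups.append(synth_replicates(spec, seed=int(child.generate_state(1)[0] % 2**31)))
    return ExperimentTable(
        molecule=molecule, metric=metric, timepoint_h=timepoint_h, groups=tuple(groups)
    )


# ---------------------------------------------------------------------------
# Synthetic frames


def _place_disks(spec: ImageSpec, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample non-overlapping disk centres (row, col)."""
    margin = spec.disk_radius + 1
    min_sep = 2 * spec.disk_radius + 2
    centres: list[tuple[int, int]] = []
    attempts = 0
    max_attempts = 1000 * max(spec.n_cells, 1)
    while len(centres) < spec.n_cells:
        if attempts >= max_attempts:
            raise PlacementError(
                f"could not place {spec.n_cells} non-overlapping disks of "
                f"radius {spec.disk_radius} in {spec.width}x{spec.height}; "
                "use fewer or smaller disks"
            )
        attempts += 1
        r = int(rng.integers(margin, spec.height - margin))
        c = int(rng.integers(margin, spec.width - margin))
        if all((r - r2) ** 2 + (c - c2) ** 2 >= min_sep**2 for r2, c2 in centres):
            centres.append((r, c))
    return np.array(centres, dtype=int).reshape(-1, 2)


def _paint_disks(
    shape: tuple[int, int], centres: np.ndarray, radius: int, intensity: float,
    background: float,
) -> np.ndarray:
    img = np.full(shape, background, dtype=float)
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    for r, c in centres:
        img[(yy - r) ** 2 + (xx - c) ** 2 <= radius**2] = intensity
    return img


def synth_frame(spec: ImageSpec) -> tuple[TwoChannelFrame, FrameTruth]:
    """Generate one two-channel frame plus its ground truth.

    The nuclear channel shows every cell; the reporter channel shows the
    stained subset (the first round(fraction * n) placed disks, in a
    shuffled placement order, so the stained set is random but exact in
    size). Gaussian noise with sd ``noise_sd`` is added to both channels
    and intensities are clipped to the 16-bit range.
    """
    rng = np.random.default_rng(spec.seed)
    centres = (
        _place_disks(spec, rng) if spec.n_cells > 0 else np.empty((0, 2), dtype=int)
    )
    n_stained = round(spec.stained_fraction * spec.n_cells)
    shape = (spec.height, spec.width)
    nuclear = _paint_disks(
        shape, centres, spec.disk_radius, spec.nuclear_intensity, spec.background
    )
    reporter = _paint_disks(
        shape, centres[:n_stained], spec.disk_radius, spec.reporter_intensity,
        spec.background,
    )
    if spec.noise_sd > 0:
        nuclear = nuclear + rng.normal(0.0, spec.noise_sd, shape)
        reporter = reporter + rng.normal(0.0, spec.noise_sd, shape)
    nuclear = np.clip(np.round(nuclear), 0, 65535).astype(np.uint16)
    reporter = np.clip(np.round(reporter), 0, 65535).astype(np.uint16)
    frame = TwoChannelFrame(
        nuclear_channel=nuclear, reporter_channel=reporter, provenance="synthetic"
    )
    truth = FrameTruth(
        n_cells=spec.n_cells,
        n_stained=n_stained,
        centroids_xy=tuple((float(c), float(r)) for r, c in centres),
        stained_flags=tuple(i < n_stained for i in range(spec.n_cells)),
    )
    return frame, truth


def truth_to_json(truth: FrameTruth, path: str | Path) -> None:
    import json

    Path(path).write_text(
        json.dumps(
            {
                "n_cells": truth.n_cells,
                "n_stained": truth.n_stained,
                "centroids_xy_px": [list(c) for c in truth.centroids_xy],
                "stained_flags": list(truth.stained_flags),
            },
            indent=2,
        )
    )
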
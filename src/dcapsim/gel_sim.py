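"""Deterministic agarose-gel model and the inverse band-detection step.

Migration follows the standard empirical law for agarose: distance is
affine in log10(fragment size), so larger fragments migrate less.
Staining is ethidium-bromide-like and mass-proportional: a band's
intensity is proportional to fragment length x molarity, normalized
within the lane.  Fragments whose migration positions fall closer than
``merge_distance`` co-migrate into a single band; fragments outside the
detectable size range run off the gel and are dropped (their mass is
still accounted for, so band intensities within a lane sum to <= 1).

There is no diffusion or lane-smile model.  An optional seeded
multiplicative intensity noise is available for estimator-robustness
simulations and is off by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "GelModel",
    "Band",
    "Lane",
    "LaneObservation",
    "lane_from_fragments",
    "detect_bands",
    "render_gel",
    "render_gel_png",
]


@dataclass(frozen=True)
class GelModel:
    """Parameters of the gel and of band detection.

    ``percent_agarose`` is display metadata (the model itself is the
    affine migration map).  Defaults are tuned to a 2.5 % gel resolving
    20-1500 bp: the 26-31 bp assay fragments are visible but faint.
    """

    percent_agarose: float = 2.5
    a: float = 10.0              # migration intercept (arbitrary gel units)
    b: float = 3.0               # slope per log10(bp); > 0
    min_size: int = 20
    max_size: int = 1500
    merge_distance: float = 0.05
    detect_threshold: float = 0.01   # min band intensity as fraction of lane total
    noise_sd: float = 0.0            # multiplicative intensity noise, off by default
    seed: int = 0

    def __post_init__(self):
        if self.b <= 0:
            raise ValueError("b must be > 0 (larger fragments migrate less)")
        if not self.min_size < self.max_size:
            raise ValueError("min_size must be < max_size")

    def migration(self, size: float) -> float:
        return self.a - self.b * math.log10(size)


@dataclass(frozen=True)
class Band:
    """One stained band: representative size, lane-relative intensity."""

    size: float
    intensity: float
    members: Tuple[float, ...] = ()


@dataclass(frozen=True)
class Lane:
    """Bands plus the off-gel fragments dropped from view."""

    bands: Tuple[Band, ...]
    dropped: Tuple[Tuple[float, float], ...] = ()  # (size, mass fraction)

    @property
    def total_intensity(self) -> float:
        return sum(b.intensity for b in self.bands)


@dataclass(frozen=True)
class LaneObservation:
    """What a reader of the gel records: band sizes with intensities.

    Intensities are on a common arbitrary scale within the lane and may
    be None when only sizes were scored.
    """

    bands: Tuple[Tuple[float, Optional[float]], ...]

    def sizes(self) -> List[float]:
        return [s for s, _ in self.bands]


def lane_from_fragments(
    fragments: Sequence[Tuple[float, float]], model: GelModel = GelModel()
) -> Lane:
    """Render (length, molarity) fragments into merged, normalized bands."""
    for length, mol in fragments:
        if length <= 0 or mol < 0:
            raise ValueError("lengths must be positive and molarities nonnegative")
    total_mass = sum(length * mol for length, mol in fragments)
    if total_mass == 0:
        return Lane(bands=())
    visible = []
    dropped = []
    for length, mol in fragments:
        mass = length * mol / total_mass
        if mass == 0:
            continue
        if model.min_size <= length <= model.max_size:
            visible.append((length, mass))
        else:
            dropped.append((float(length), mass))
    # merge co-migrating fragments (chain clustering on migration distance)
    visible.sort(key=lambda t: model.migration(t[0]))
    bands: List[Band] = []
    cluster: List[Tuple[float, float]] = []

    def flush():
        if not cluster:
            return
        mass = sum(m for _, m in cluster)
        size = sum(s * m for s, m in cluster) / mass  # mass-weighted mean
        bands.append(Band(size=size, intensity=mass,
                          members=tuple(s for s, _ in cluster)))

    for size, mass in visible:
        if cluster and (
            model.migration(size) - model.migration(cluster[-1][0])
        ) >= model.merge_distance:
            flush()
            cluster = []
        cluster.append((size, mass))
    flush()
    bands.sort(key=lambda b: -b.size)
    return Lane(bands=tuple(bands), dropped=tuple(dropped))


def detect_bands(lane: Lane, model: GelModel = GelModel()) -> LaneObservation:
    """Bands at or above the detection threshold, as an observation.

    With ``noise_sd`` > 0 a seeded multiplicative noise is applied to
    the intensities before thresholding.
    """
    intensities = np.array([b.intensity for b in lane.bands], dtype=float)
    if model.noise_sd > 0 and len(intensities):
        rng = np.random.default_rng(model.seed)
        intensities = np.clip(
            intensities * (1.0 + model.noise_sd * rng.standard_normal(len(intensities))),
            0.0, None,
        )
    out = [
        (band.size, float(i))
        for band, i in zip(lane.bands, intensities)
        if i >= model.detect_threshold
    ]
    return LaneObservation(bands=tuple(out))


# ---------------------------------------------------------------------------
# Rendering

_DEFAULT_MARKER = (1000, 500, 400, 300, 200, 150, 100, 50)
_ROWS = 28


def _intensity_char(x: float) -> str:
    if x >= 0.35:
        return "#"
    if x >= 0.15:
        return "="
    if x >= 0.05:
        return "-"
    return "."


def render_gel(
    lanes: Sequence[Tuple[str, Lane]],
    model: GelModel = GelModel(),
    marker: Sequence[int] = _DEFAULT_MARKER,
) -> str:
    """Deterministic ASCII gel: identical inputs give identical bytes.

    The first column is a size marker; each lane is a labelled column in
    which band rows are drawn with characters scaled by intensity.
    """
    if not lanes:
        raise ValueError("at least one lane is required")
    d_top = model.migration(model.max_size)
    d_bot = model.migration(model.min_size)

    def row_of(size: float) -> int:
        d = min(max(model.migration(size), d_top), d_bot)
        return round((d - d_top) / (d_bot - d_top) * (_ROWS - 1))

    width = 8
    header = f"{'bp':>6} |" + "".join(f"{label[:width - 1]:>{width}}" for label in
                                      ["M"] + [lab for lab, _ in lanes])
    grid = [[" " * width for _ in range(len(lanes) + 1)] for _ in range(_ROWS)]
    axis = [""] * _ROWS
    for m in marker:
        if model.min_size <= m <= model.max_size:
            r = row_of(m)
            grid[r][0] = f"{'===':>{width}}"
            axis[r] = str(m)
    for j, (_, lane) in enumerate(lanes, start=1):
        for band in lane.bands:
            r = row_of(band.size)
            ch = _intensity_char(band.intensity) * 3
            grid[r][j] = f"{ch:>{width}}"
    lines = [header, f"{'':>6} +" + "-" * (width * (len(lanes) + 1))]
    for r in range(_ROWS):
        lines.append(f"{axis[r]:>6} |" + "".join(grid[r]))
    return "\n".join(lines) + "\n"


def render_gel_png(
    lanes: Sequence[Tuple[str, Lane]],
    path,
    model: GelModel = GelModel(),
    marker: Sequence[int] = _DEFAULT_MARKER,
) -> None:
    """Optional raster rendering (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1 + len(lanes), 5))
    all_lanes = [("M", Lane(tuple(Band(float(m), 0.5) for m in marker)))] + list(lanes)
    for x, (label, lane) in enumerate(all_lanes):
        for band in lane.bands:
            y = model.migration(band.size)
            ax.plot([x - 0.3, x + 0.3], [y, y], lw=2 + 6 * band.intensity,
                    color="white", solid_capstyle="butt")
    ax.set_facecolor("black")
    ax.set_xticks(range(len(all_lanes)))
    ax.set_xticklabels([label for label, _ in all_lanes])
    ax.set_ylim(model.migration(model.min_size), model.migration(model.max_size))
    ax.set_ylabel("migration")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
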
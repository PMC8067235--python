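"""Quantification of periprobe immunofluorescence.

Pipeline (per 16-bit single-channel image of a coronal section through the
implant track): ten 50 x 2348 um rectangular bands are stacked upward from
the manually supplied implant-tip center; in each band the explanted-probe
track is detected as the contiguous low-intensity column interval around
the band center; column-mean intensities are folded at the two track edges
into left/right distance profiles; sides and bands are averaged by distance
from the probe surface; the profile is normalized to the background beyond
500 um and binned into ten 50 um intervals.  Group comparisons use one-way
ANOVA on whole-region mean intensities and two-way ANOVA (material x
distance bin) on the binned profiles, both with Tukey HSD post-hoc tests.

Image conventions: row 0 is the top of the image, the tip center is given
as (row, col) in pixels, and "upward" (toward the cortical surface along
the track) means decreasing row index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

__all__ = [
    "FluorescenceImage",
    "ROIBand",
    "IntensityProfile",
    "BinnedProfile",
    "ProbeDetectionError",
    "define_roi_bands",
    "detect_probe_region",
    "band_profile",
    "side_and_band_average",
    "normalize_background",
    "bin_profile",
    "image_profile",
    "mean_region_intensity",
    "group_stats_oneway",
    "group_stats_twoway",
    "overlay_with_strain",
]

BAND_HEIGHT_UM = 50.0
BAND_WIDTH_UM = 2348.0
N_BANDS = 10
BACKGROUND_CUTOFF_UM = 500.0
BIN_WIDTH_UM = 50.0
CHANNELS = ("GFAP", "Iba1", "CD68", "IgG")


class ProbeDetectionError(RuntimeError):
    """No low-intensity track interval found in a band."""


@dataclass
class FluorescenceImage:
    """Single-channel 16-bit fluorescence raster with acquisition metadata."""

    data: np.ndarray
    pixel_size: float  # um / px
    channel: str = "GFAP"
    material: str = ""
    timepoint: str = "4w"
    tip_center: tuple[int, int] | None = None  # (row, col), px

    def __post_init__(self):
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.data.min() < 0 or self.data.max() > 65535:
            raise ValueError("intensities must lie within the 16-bit range")

    def save(self, path) -> None:
        """Write TIFF plus a YAML sidecar with the metadata."""
        import tifffile

        path = Path(path)
        tifffile.imwrite(path, self.data.astype(np.uint16))
        meta = {
            "pixel_size": self.pixel_size,
            "channel": self.channel,
            "material": self.material,
            "timepoint": self.timepoint,
            "tip_center": list(self.tip_center) if self.tip_center else None,
        }
        path.with_suffix(".yaml").write_text(yaml.safe_dump(meta))

    @classmethod
    def load(cls, path) -> "FluorescenceImage":
        import tifffile

        path = Path(path)
        meta = yaml.safe_load(path.with_suffix(".yaml").read_text())
        tip = meta.get("tip_center")
        return cls(
            data=tifffile.imread(path),
            pixel_size=float(meta["pixel_size"]),
            channel=meta.get("channel", "GFAP"),
            material=meta.get("material", ""),
            timepoint=meta.get("timepoint", "4w"),
            tip_center=tuple(tip) if tip else None,
        )


@dataclass(frozen=True)
class ROIBand:
    """One 50 x 2348 um analysis rectangle (pixel slice bounds)."""

    index: int
    row0: int
    row1: int
    col0: int
    col1: int

    def extract(self, data: np.ndarray) -> np.ndarray:
        return data[self.row0 : self.row1, self.col0 : self.col1]


@dataclass
class IntensityProfile:
    """Mean intensity vs distance (um) from the probe surface."""

    distance: np.ndarray
    intensity: np.ndarray
    normalized: bool = False


@dataclass
class BinnedProfile:
    """Ten 50-um bin means over 0-500 um; NaN marks an empty bin."""

    values: np.ndarray
    bin_edges: np.ndarray = field(
        default_factory=lambda: np.arange(0.0, 501.0, BIN_WIDTH_UM)
    )
    replicate: str = ""


def define_roi_bands(image: FluorescenceImage,
                     tip_center: tuple[int, int] | None = None) -> list[ROIBand]:
    """Ten bands stacked upward from the tip center, width centered on it."""
    tip = tip_center or image.tip_center
    if tip is None:
        raise ValueError("tip_center must be supplied")
    trow, tcol = tip
    h = int(round(BAND_HEIGHT_UM / image.pixel_size))
    w = int(round(BAND_WIDTH_UM / image.pixel_size))
    col0, col1 = tcol - w // 2, tcol - w // 2 + w
    if trow - N_BANDS * h < 0:
        raise ValueError(
            f"need {N_BANDS * BAND_HEIGHT_UM:.0f} um above the tip inside the image"
        )
    if col0 < 0 or col1 > image.data.shape[1]:
        raise ValueError("band width exceeds the image extent")
    return [
        ROIBand(index=i + 1, row0=trow - (i + 1) * h, row1=trow - i * h,
                col0=col0, col1=col1)
        for i in range(N_BANDS)
    ]


def detect_probe_region(band: np.ndarray, mad_factor: float = 2.0):
    """Detect the probe-track column interval in a band.

    The column-mean profile is thresholded at median - mad_factor * MAD
    (scaled MAD, Gaussian-consistent); the track is the longest contiguous
    below-threshold run containing the band center.  Returns (left, right)
    as inclusive column indices of the track.
    """
    prof = band.mean(axis=0)
    med = np.median(prof)
    mad = 1.4826 * np.median(np.abs(prof - med))
    thr = med - mad_factor * mad
    below = prof < thr
    if not below.any():
        raise ProbeDetectionError("no columns below the track threshold")
    # contiguous runs of below-threshold columns
    idx = np.flatnonzero(below)
    splits = np.where(np.diff(idx) > 1)[0] + 1
    runs = np.split(idx, splits)
    center = len(prof) // 2
    containing = [r for r in runs if r[0] <= center <= r[-1]]
    if containing:
        run = containing[0]
    else:
        run = max(runs, key=len)
        if not len(run):
            raise ProbeDetectionError("no track interval found")
    return int(run[0]), int(run[-1])


def band_profile(band: np.ndarray, interval: tuple[int, int],
                 pixel_size: float):
    """Left/right distance profiles of the column-mean intensity.

    Distances are measured from the track edge (probe surface), at pixel
    centers: the first tissue column sits at half a pixel from the edge.
    Returns two IntensityProfile objects (left side, right side).
    """
    i0, i1 = interval
    colmean = band.mean(axis=0)
    cols = np.arange(len(colmean), dtype=float)
    left_cols = cols[:i0]
    right_cols = cols[i1 + 1 :]
    left = IntensityProfile(
        distance=((i0 - 0.5) - left_cols)[::-1] * pixel_size,
        intensity=colmean[:i0][::-1],
    )
    right = IntensityProfile(
        distance=(right_cols - (i1 + 0.5)) * pixel_size,
        intensity=colmean[i1 + 1 :],
    )
    return left, right


def side_and_band_average(profiles, grid: np.ndarray | None = None
                          ) -> IntensityProfile:
    """Average profiles over sides, then over bands, on a common grid.

    ``profiles``: iterable over bands of (left, right) IntensityProfile
    pairs (either side may be None for a failed detection side).
    """
    bands = [
        [p for p in pair if p is not None and len(p.distance)]
        for pair in profiles
    ]
    bands = [b for b in bands if b]
    if not bands:
        raise ValueError("no valid band profiles to average")
    if grid is None:
        dmax = min(min(p.distance[-1] for p in b) for b in bands)
        step = min(np.min(np.diff(p.distance)) for b in bands for p in b
                   if len(p.distance) > 1)
        grid = np.arange(0.0, dmax + step / 2, step)
    band_means = []
    for b in bands:
        sides = [np.interp(grid, p.distance, p.intensity) for p in b]
        band_means.append(np.mean(sides, axis=0))
    return IntensityProfile(distance=grid,
                            intensity=np.mean(band_means, axis=0))


def normalize_background(profile: IntensityProfile,
                         cutoff: float = BACKGROUND_CUTOFF_UM
                         ) -> IntensityProfile:
    """Divide by the mean intensity at distances beyond the cutoff."""
    far = profile.distance > cutoff
    if not far.any():
        raise ValueError(f"profile does not extend beyond {cutoff} um")
    bg = float(profile.intensity[far].mean())
    if bg <= 0:
        raise ValueError("non-positive background level")
    return IntensityProfile(distance=profile.distance,
                            intensity=profile.intensity / bg, normalized=True)


def bin_profile(profile: IntensityProfile, replicate: str = "") -> BinnedProfile:
    """Mean normalized intensity in ten 50-um bins over 0-500 um."""
    edges = np.arange(0.0, 501.0, BIN_WIDTH_UM)
    vals = np.full(N_BANDS, np.nan)
    for i in range(N_BANDS):
        m = (profile.distance >= edges[i]) & (profile.distance < edges[i + 1])
        if m.any():
            vals[i] = profile.intensity[m].mean()
    return BinnedProfile(values=vals, bin_edges=edges, replicate=replicate)


def image_profile(image: FluorescenceImage,
                  tip_center: tuple[int, int] | None = None,
                  min_valid_bands: int = 8):
    """Full per-image pipeline: bands -> detection -> averaged normalized
    profile and its binned form.  Bands with failed detection are dropped;
    fewer than ``min_valid_bands`` valid bands is an error."""
    bands = define_roi_bands(image, tip_center)
    pairs = []
    for b in bands:
        sub = b.extract(image.data)
        try:
            interval = detect_probe_region(sub)
        except ProbeDetectionError:
            continue
        pairs.append(band_profile(sub, interval, image.pixel_size))
    if len(pairs) < min_valid_bands:
        raise ProbeDetectionError(
            f"only {len(pairs)} of {N_BANDS} bands had a detectable track"
        )
    avg = side_and_band_average(pairs)
    norm = normalize_background(avg)
    return norm, bin_profile(norm)


def mean_region_intensity(image: FluorescenceImage,
                          tip_center: tuple[int, int] | None = None,
                          height_above: float = 550.0,
                          height_below: float = 200.0,
                          width: float = 1000.0) -> float:
    """Mean raw intensity over the wide implant-site rectangle.

    Default geometry: 750 um tall (550 above, 200 below the tip), 1000 um
    wide, centered horizontally on the probe.
    """
    tip = tip_center or image.tip_center
    if tip is None:
        raise ValueError("tip_center must be supplied")
    trow, tcol = tip
    px = image.pixel_size
    r0 = trow - int(round(height_above / px))
    r1 = trow + int(round(height_below / px))
    w = int(round(width / px))
    c0, c1 = tcol - w // 2, tcol - w // 2 + w
    if r0 < 0 or r1 > image.data.shape[0] or c0 < 0 or c1 > image.data.shape[1]:
        raise ValueError("mean-intensity region exceeds the image bounds")
    return float(image.data[r0:r1, c0:c1].mean())


# ---------------------------------------------------------------------------
# group statistics


def group_stats_oneway(values_by_group: dict[str, np.ndarray]):
    """One-way ANOVA across material groups plus Tukey HSD post-hoc.

    Returns (anova: DataFrame, tukey: DataFrame).  Degenerate input (zero
    within-group variance everywhere) is flagged instead of raising.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    if len(groups) < 2 or any(len(v) < 2 for v in groups.values()):
        raise ValueError("need >= 2 groups with >= 2 replicates each")
    arrays = list(groups.values())
    degenerate = all(np.ptp(a) == 0 for a in arrays)
    if degenerate and len({a[0] for a in arrays}) == 1:
        anova = pd.DataFrame(
            {"F": [0.0], "p": [1.0], "degenerate": [True]}
        )
        tukey = pd.DataFrame(
            columns=["group1", "group2", "meandiff", "p_adj", "reject"]
        )
        return anova, tukey
    F, p = stats.f_oneway(*arrays)
    anova = pd.DataFrame({"F": [F], "p": [p], "degenerate": [False]})
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    vals = np.concatenate(arrays)
    labels = np.concatenate([[k] * len(v) for k, v in groups.items()])
    res = pairwise_tukeyhsd(vals, labels)
    tukey = pd.DataFrame(
        res.summary().data[1:],
        columns=[c.strip() for c in res.summary().data[0]],
    ).rename(columns={"p-adj": "p_adj"})
    return anova, tukey


def group_stats_twoway(binned: pd.DataFrame):
    """Two-way ANOVA (material x distance bin) plus per-bin Tukey tests.

    ``binned`` columns: material, bin (int 1-10 or bin label), intensity,
    replicate.  Returns (anova table, {bin: tukey DataFrame}).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    df = binned.dropna(subset=["intensity"]).copy()
    counts = df.groupby(["material", "bin"], observed=True).size()
    full = df["material"].nunique() * df["bin"].nunique()
    if len(counts) < full:
        raise ValueError("design has empty material x bin cells")
    model = smf.ols("intensity ~ C(material) * C(bin)", data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    per_bin = {}
    for b, sub in df.groupby("bin", observed=True):
        if sub["material"].nunique() < 2:
            continue
        res = pairwise_tukeyhsd(sub["intensity"].to_numpy(),
                                sub["material"].to_numpy())
        per_bin[b] = pd.DataFrame(
            res.summary().data[1:],
            columns=[c.strip() for c in res.summary().data[0]],
        ).rename(columns={"p-adj": "p_adj"})
    return anova, per_bin


def overlay_with_strain(intensity_profiles: dict, strain_profile,
                        n_grid: int = 101):
    """Overlay min-max normalized intensity and strain curves; compare order.

    ``intensity_profiles``: {material: (distance_um, intensity)};
    ``strain_profile``: either a single (distance_mm_or_um, strain) tuple
    applied to all materials or a {material: (distance, strain)} dict.
    Distances are brought to a common [0, dmax] grid.  The magnitude
    ordering of materials (by mean curve level before normalization) is
    reported for each modality along with whether the orderings agree.
    """
    from .postprocess import minmax_normalize

    if not isinstance(strain_profile, dict):
        strain_profile = {m: strain_profile for m in intensity_profiles}
    if set(strain_profile) != set(intensity_profiles):
        raise ValueError("modalities cover different material sets")
    dmax = min(
        min(np.max(d) for d, _ in intensity_profiles.values()),
        min(np.max(d) for d, _ in strain_profile.values()),
    )
    grid = np.linspace(0.0, dmax, n_grid)
    out = {"distance": grid, "intensity": {}, "strain": {}}
    level_i, level_s = {}, {}
    for m, (d, v) in intensity_profiles.items():
        vi = np.interp(grid, np.asarray(d, float), np.asarray(v, float))
        level_i[m] = float(vi.mean())
        out["intensity"][m] = minmax_normalize(vi)
    for m, (d, v) in strain_profile.items():
        vs = np.interp(grid, np.asarray(d, float), np.asarray(v, float))
        level_s[m] = float(vs.mean())
        out["strain"][m] = minmax_normalize(vs)
    rank_i = sorted(level_i, key=level_i.get, reverse=True)
    rank_s = sorted(level_s, key=level_s.get, reverse=True)
    out["intensity_order"] = rank_i
    out["strain_order"] = rank_s
    out["ordering_agrees"] = rank_i == rank_s
    return out
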
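"""Classification of perturbation outcomes into regulatory patterns.

Each sustained perturbation result is assigned one of three patterns by
comparing the relative changes ``df = |frequency_ratio - 1|`` and
``da = |amplitude_ratio - 1|`` against a 1% threshold:

* **R** (robust): both changes below the threshold;
* **F** (frequency-dominant): at least one change at or above the
  threshold, and the frequency changed more than the amplitude;
* **A** (amplitude-dominant): at least one change at or above the
  threshold, and the amplitude changed at least as much as the frequency.

The threshold comparison is strict (a change of exactly 1% is not R), and
the tie ``df == da`` above threshold goes to A; ties are counted and
reported because they carry essentially zero measure.  Density grids
discretize the (frequency ratio, amplitude ratio) plane into 100 x 100
equal cells holding percentages of all sustained results.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptySummaryError, ValidationError

__all__ = [
    "classify_pattern",
    "classify_table",
    "PatternSummary",
    "summarize_patterns",
    "DensityGrid",
    "build_density_grid",
    "DENSITY_COLORMAP_STOPS",
]

PATTERN_THRESHOLD = 0.01

# density ramp: white -> yellow -> red -> black with increasing density
DENSITY_COLORMAP_STOPS = ("white", "yellow", "red", "black")


def classify_pattern(
    frequency_ratio: float, amplitude_ratio: float, threshold: float = PATTERN_THRESHOLD
) -> str:
    """Classify one (frequency ratio, amplitude ratio) pair as R, F or A."""
    if frequency_ratio <= 0 or amplitude_ratio <= 0:
        raise ValidationError("ratios must be strictly positive")
    df = abs(frequency_ratio - 1.0)
    da = abs(amplitude_ratio - 1.0)
    if df < threshold and da < threshold:
        return "R"
    return "F" if df > da else "A"


def classify_table(results: pd.DataFrame, threshold: float = PATTERN_THRESHOLD) -> pd.Series:
    """Vectorized pattern labels for the sustained rows of a result table."""
    sus = results[results["status"] == "sustained"]
    df = (sus["frequency_ratio"] - 1.0).abs()
    da = (sus["amplitude_ratio"] - 1.0).abs()
    labels = np.where(
        (df < threshold) & (da < threshold), "R", np.where(df > da, "F", "A")
    )
    return pd.Series(labels, index=sus.index, name="pattern")


@dataclass
class PatternSummary:
    """Per-model R/F/A percentages over sustained results."""

    model: str
    fraction_r: float  # percent
    fraction_f: float
    fraction_a: float
    n_results: int
    n_ties: int = 0
    per_link: pd.DataFrame | None = None

    def as_row(self) -> dict:
        return {
            "model": self.model,
            "pattern_R": self.fraction_r,
            "pattern_F": self.fraction_f,
            "pattern_A": self.fraction_a,
            "n_results": self.n_results,
        }


def _fractions(labels: pd.Series) -> tuple[float, float, float]:
    n = len(labels)
    counts = labels.value_counts()
    return tuple(100.0 * counts.get(p, 0) / n for p in ("R", "F", "A"))


def summarize_patterns(
    results: pd.DataFrame,
    threshold: float = PATTERN_THRESHOLD,
    per_link: bool = False,
    factors: list | None = None,
) -> dict[str, PatternSummary]:
    """R/F/A percentage breakdown per model over sustained results.

    ``factors`` restricts the summary to a subset of weakening factors
    (commonly the 1% weakening only).  Non-sustained rows never enter the
    statistics.
    """
    data = results
    if factors is not None:
        data = data[data["factor"].isin(factors)]
    out: dict[str, PatternSummary] = {}
    for model_name, group in data.groupby("model"):
        sus = group[group["status"] == "sustained"]
        if len(sus) == 0:
            raise EmptySummaryError(f"no sustained results for model {model_name}")
        labels = classify_table(sus, threshold)
        fr, ff, fa = _fractions(labels)
        df = (sus["frequency_ratio"] - 1.0).abs()
        da = (sus["amplitude_ratio"] - 1.0).abs()
        ties = int(((df == da) & (df >= threshold)).sum())
        link_tbl = None
        if per_link:
            rows = []
            for link, lg in sus.groupby("link"):
                lr, lf, la = _fractions(classify_table(lg, threshold))
                rows.append(
                    {"link": link, "pattern_R": lr, "pattern_F": lf,
                     "pattern_A": la, "n_results": len(lg)}
                )
            link_tbl = pd.DataFrame(rows)
        out[model_name] = PatternSummary(
            model=model_name,
            fraction_r=fr,
            fraction_f=ff,
            fraction_a=fa,
            n_results=len(sus),
            n_ties=ties,
            per_link=link_tbl,
        )
    return out


def summaries_to_frame(summaries: dict[str, PatternSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.as_row() for s in summaries.values()])


@dataclass
class DensityGrid:
    """100 x 100 percentage histogram over the frequency/amplitude-ratio plane."""

    grid: np.ndarray  # (ny, nx) percentages; row 0 = lowest amplitude ratio
    freq_bounds: tuple[float, float]
    amp_bounds: tuple[float, float]
    out_of_range_percent: float
    n_results: int
    colormap_stops: tuple = DENSITY_COLORMAP_STOPS

    @property
    def shape(self):
        return self.grid.shape


def build_density_grid(
    results: pd.DataFrame,
    grid_shape: tuple[int, int] = (100, 100),
    bounds: tuple[tuple[float, float], tuple[float, float]] | None = None,
) -> DensityGrid:
    """Histogram sustained results into equal-sized ratio sub-domains.

    ``bounds`` is ``((freq_lo, freq_hi), (amp_lo, amp_hi))``; by default a
    symmetric [0.9, 1.1] window, widened to the 0.5th-99.5th percentile of
    the observed ratios when they spill outside it.  Results beyond the
    final bounds are excluded from the grid but counted in
    ``out_of_range_percent`` so the total is conserved.
    """
    sus = results[results["status"] == "sustained"]
    if len(sus) == 0:
        raise ValidationError("need at least one sustained result")
    fr = sus["frequency_ratio"].to_numpy(float)
    ar = sus["amplitude_ratio"].to_numpy(float)
    if bounds is None:
        flo, fhi = 0.9, 1.1
        alo, ahi = 0.9, 1.1
        flo = min(flo, float(np.percentile(fr, 0.5)))
        fhi = max(fhi, float(np.percentile(fr, 99.5)))
        alo = min(alo, float(np.percentile(ar, 0.5)))
        ahi = max(ahi, float(np.percentile(ar, 99.5)))
    else:
        (flo, fhi), (alo, ahi) = bounds
    if not (fhi > flo and ahi > alo):
        raise ValidationError("degenerate density-grid bounds")
    ny, nx = grid_shape
    hist, _, _ = np.histogram2d(
        ar, fr, bins=(ny, nx), range=((alo, ahi), (flo, fhi))
    )
    inside = int(hist.sum())
    n = len(sus)
    return DensityGrid(
        grid=100.0 * hist / n,
        freq_bounds=(flo, fhi),
        amp_bounds=(alo, ahi),
        out_of_range_percent=100.0 * (n - inside) / n,
        n_results=n,
    )


def plot_density(grid: DensityGrid, ax=None, title: str | None = None):
    """Render a density grid with the white-yellow-red-black ramp."""
    import matplotlib.pyplot as plt
    from matplotlib.colors import LinearSegmentedColormap

    cmap = LinearSegmentedColormap.from_list("density", grid.colormap_stops)
    if ax is None:
        _, ax = plt.subplots(figsize=(4.2, 4))
    vmax = max(grid.grid.max(), 1e-12)
    im = ax.imshow(
        grid.grid,
        origin="lower",
        extent=(*grid.freq_bounds, *grid.amp_bounds),
        aspect="auto",
        cmap=cmap,
        vmin=0.0,
        vmax=vmax,
    )
    ax.set_xlabel("frequency ratio")
    ax.set_ylabel("amplitude ratio")
    if title:
        ax.set_title(title)
    return ax, im
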
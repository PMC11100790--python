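"""Glycan microarray spot quantification and statistics.

A printed glycan array carries replicate spots per glycan plus negative
control spots (printing buffer only).  For each spot the mean intensity in
a disk is corrected by the median of a local background annulus; corrected
values are normalized within each array (division by the array-wide mean
corrected signal) to absorb slide-to-slide changes in imaging conditions.

Two calls are made per glycan:

* detection - the mean corrected signal must exceed twice the standard
  deviation of the local background (strict inequality);
* significance - a Welch t test of the glycan replicates against the pooled
  negative controls, with family-wise adjustment by a Dunnett-style
  procedure.  Because Dunnett's test with unequal variances has no closed
  form, the adjustment is evaluated by seeded Monte Carlo on the joint null
  distribution of the Welch statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ArrayLayout",
    "SpotQuant",
    "quantify_spot",
    "quantify_array",
    "normalize_within_array",
    "detection_call",
    "welch_t",
    "MonteCarloDunnett",
    "dunnett_vs_control",
    "analyze_array",
]


@dataclass(frozen=True)
class ArrayLayout:
    """Geometry and identity of every spot on one array.

    ``glycan_positions`` has shape (n_glycans, n_replicates, 2) holding
    (row, col) centers in pixels; ``control_positions`` has shape
    (n_controls, 2).  The background annulus must enclose the spot disk.
    """

    glycans: Tuple[str, ...]
    glycan_positions: np.ndarray
    control_positions: np.ndarray
    spot_radius: float
    annulus_radii: Tuple[float, float]

    def __post_init__(self) -> None:
        gp = np.asarray(self.glycan_positions, dtype=float)
        cp = np.asarray(self.control_positions, dtype=float)
        if gp.ndim != 3 or gp.shape[0] != len(self.glycans) or gp.shape[2] != 2:
            raise ValueError("glycan_positions must be (n_glycans, n_replicates, 2)")
        if cp.ndim != 2 or cp.shape[1] != 2:
            raise ValueError("control_positions must be (n_controls, 2)")
        inner, outer = self.annulus_radii
        if not (self.spot_radius > 0 and inner > self.spot_radius and outer > inner):
            raise ValueError("require 0 < spot_radius < annulus inner < annulus outer")
        object.__setattr__(self, "glycans", tuple(self.glycans))
        object.__setattr__(self, "glycan_positions", gp)
        object.__setattr__(self, "control_positions", cp)

    @property
    def n_replicates(self) -> int:
        return self.glycan_positions.shape[1]

    def all_positions(self) -> np.ndarray:
        return np.vstack(
            [self.glycan_positions.reshape(-1, 2), self.control_positions]
        )

    @classmethod
    def default_grid(
        cls,
        n_glycans: int = 100,
        n_replicates: int = 4,
        n_controls: int = 8,
        glycans: Optional[Sequence[str]] = None,
        pitch: float = 16.0,
        origin: Tuple[float, float] = (12.0, 12.0),
        n_cols: int = 24,
        spot_radius: float = 4.0,
        annulus_radii: Tuple[float, float] = (5.5, 7.5),
    ) -> "ArrayLayout":
        """Row-major grid layout: one set of controls first, one set last.

        The default emulates a commercial 100-glycan array printed in 4
        replicate spots with two sets of 4 negative-control spots.
        """
        if n_controls % 2 != 0:
            raise ValueError("controls are split into two sets; need an even count")
        if glycans is None:
            glycans = tuple(f"glycan_{i + 1:03d}" for i in range(n_glycans))
        if len(glycans) != n_glycans:
            raise ValueError("glycan name count mismatch")
        n_spots = n_glycans * n_replicates + n_controls
        rows = origin[0] + pitch * (np.arange(n_spots) // n_cols)
        cols = origin[1] + pitch * (np.arange(n_spots) % n_cols)
        centers = np.stack([rows, cols], axis=1)
        half = n_controls // 2
        control_positions = np.vstack([centers[:half], centers[n_spots - half :]])
        glycan_positions = centers[half : n_spots - half].reshape(
            n_glycans, n_replicates, 2
        )
        return cls(
            glycans=tuple(glycans),
            glycan_positions=glycan_positions,
            control_positions=control_positions,
            spot_radius=spot_radius,
            annulus_radii=annulus_radii,
        )

    @property
    def image_shape(self) -> Tuple[int, int]:
        """Smallest image plane containing every annulus, padded by 2 px."""
        pos = self.all_positions()
        outer = self.annulus_radii[1]
        return (
            int(np.ceil(pos[:, 0].max() + outer)) + 3,
            int(np.ceil(pos[:, 1].max() + outer)) + 3,
        )


@dataclass(frozen=True)
class SpotQuant:
    """Quantification of one spot before/after within-array normalization."""

    raw_signal: float
    local_background: float
    corrected: float
    background_sd: float
    normalized: Optional[float] = None


def _disk_and_annulus(
    image: np.ndarray,
    center: Tuple[float, float],
    spot_radius: float,
    annulus_radii: Tuple[float, float],
) -> Tuple[np.ndarray, np.ndarray]:
    cy, cx = float(center[0]), float(center[1])
    inner, outer = annulus_radii
    h, w = image.shape
    if (
        cy - outer < -0.5
        or cx - outer < -0.5
        or cy + outer > h - 0.5
        or cx + outer > w - 0.5
    ):
        raise ValueError("spot annulus extends outside the image")
    y0, y1 = int(np.floor(cy - outer)), int(np.ceil(cy + outer)) + 1
    x0, x1 = int(np.floor(cx - outer)), int(np.ceil(cx + outer)) + 1
    y0, x0 = max(y0, 0), max(x0, 0)
    yy, xx = np.ogrid[y0:y1, x0:x1]
    d = np.hypot(yy - cy, xx - cx)
    patch = image[y0:y1, x0:x1]
    disk = patch[d <= spot_radius]
    annulus = patch[(d >= inner) & (d <= outer)]
    return disk, annulus


def quantify_spot(
    image: np.ndarray,
    center: Tuple[float, float],
    spot_radius: float,
    annulus_radii: Tuple[float, float],
) -> SpotQuant:
    """Mean disk signal minus the median of a local background annulus.

    The annulus median is robust to bleed from neighbouring spots; the
    annulus standard deviation feeds the detection rule.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("image must be 2-D")
    disk, annulus = _disk_and_annulus(img, center, spot_radius, annulus_radii)
    if disk.size == 0 or annulus.size < 2:
        raise ValueError("degenerate spot geometry")
    raw = float(disk.mean())
    background = float(np.median(annulus))
    return SpotQuant(
        raw_signal=raw,
        local_background=background,
        corrected=raw - background,
        background_sd=float(annulus.std(ddof=1)),
    )


def quantify_array(image: np.ndarray, layout: ArrayLayout) -> pd.DataFrame:
    """Quantify every spot of an array; returns one row per spot.

    Columns: glycan (``"control"`` for negative controls), replicate,
    is_control, raw, background, corrected, background_sd, normalized.
    Normalization divides corrected values by the array-wide mean corrected
    signal over all spots (controls included).
    """
    rows = []
    for gi, name in enumerate(layout.glycans):
        for ri in range(layout.n_replicates):
            q = quantify_spot(
                image,
                tuple(layout.glycan_positions[gi, ri]),
                layout.spot_radius,
                layout.annulus_radii,
            )
            rows.append((name, ri, False, q.raw_signal, q.local_background, q.corrected, q.background_sd))
    for ci, pos in enumerate(layout.control_positions):
        q = quantify_spot(image, tuple(pos), layout.spot_radius, layout.annulus_radii)
        rows.append(("control", ci, True, q.raw_signal, q.local_background, q.corrected, q.background_sd))
    df = pd.DataFrame(
        rows,
        columns=[
            "glycan",
            "replicate",
            "is_control",
            "raw",
            "background",
            "corrected",
            "background_sd",
        ],
    )
    corrected = df["corrected"].to_numpy()
    if corrected.mean() > 0:
        df["normalized"] = normalize_within_array(corrected)
    else:
        # a blank/degenerate array has no meaningful within-array normalizer
        df["normalized"] = np.nan
    return df


def normalize_within_array(corrected: np.ndarray) -> np.ndarray:
    """Divide corrected spot values by their array-wide mean.

    Makes values dimensionless and invariant to a multiplicative gain
    applied to the whole array image.  Requires a positive normalizer.
    """
    vals = np.asarray(corrected, dtype=float)
    norm = vals.mean()
    if not norm > 0:
        raise ValueError("array-wide mean corrected signal must be positive")
    return vals / norm


def detection_call(corrected_mean: float, background_sd: float) -> bool:
    """Detected iff the corrected signal strictly exceeds 2x background SD."""
    if background_sd < 0:
        raise ValueError("background SD must be nonnegative")
    return bool(corrected_mean > 2.0 * background_sd)


def welch_t(group: np.ndarray, control: np.ndarray) -> float:
    """Welch t statistic of one group versus the control group."""
    g = np.asarray(group, dtype=float)
    c = np.asarray(control, dtype=float)
    se2 = g.var(ddof=1) / g.size + c.var(ddof=1) / c.size
    return float((g.mean() - c.mean()) / np.sqrt(se2))


def _welch_t_batch(groups: np.ndarray, control: np.ndarray) -> np.ndarray:
    """Welch t statistics for batched experiments.

    ``groups`` has shape (n_experiments, n_groups, n); ``control`` has shape
    (n_experiments, n_control).  Returns (n_experiments, n_groups).
    """
    gm = groups.mean(axis=2)
    gv = groups.var(axis=2, ddof=1)
    cm = control.mean(axis=1)[:, None]
    cv = control.var(axis=1, ddof=1)[:, None]
    return (gm - cm) / np.sqrt(gv / groups.shape[2] + cv / control.shape[1])


class MonteCarloDunnett:
    """Dunnett-style many-to-one adjustment of Welch statistics.

    The family-wise null distribution of ``max_j |T_j|`` over the Welch
    statistics of ``n_groups`` groups against a shared control is simulated
    (all samples standard normal) with a fixed seed; the adjusted p-value of
    an observed statistic ``t`` is ``(1 + #{draws >= |t|}) / (n_draws + 1)``,
    which is monotone in ``|t|`` by construction.
    """

    def __init__(
        self,
        n_groups: int,
        group_size: int,
        control_size: int,
        n_draws: int = 100_000,
        seed: int = 0,
        chunk: int = 20_000,
    ) -> None:
        if group_size < 2 or control_size < 2:
            raise ValueError("each group and the control need at least 2 replicates")
        self.n_groups = int(n_groups)
        self.group_size = int(group_size)
        self.control_size = int(control_size)
        self.n_draws = int(n_draws)
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        maxima = []
        done = 0
        while done < self.n_draws:
            m = min(chunk, self.n_draws - done)
            g = rng.standard_normal((m, self.n_groups, self.group_size))
            c = rng.standard_normal((m, self.control_size))
            t = _welch_t_batch(g, c)
            maxima.append(np.abs(t).max(axis=1))
            done += m
        self._null_sorted = np.sort(np.concatenate(maxima))

    def adjust(self, tstats: np.ndarray) -> np.ndarray:
        """Family-wise adjusted p-values for observed Welch statistics."""
        t = np.atleast_1d(np.abs(np.asarray(tstats, dtype=float)))
        n_ge = self.n_draws - np.searchsorted(self._null_sorted, t, side="left")
        return (1.0 + n_ge) / (self.n_draws + 1.0)

    def critical_value(self, alpha: float = 0.05) -> float:
        """|t| threshold controlling the family-wise error rate at alpha."""
        return float(np.quantile(self._null_sorted, 1.0 - alpha))


def dunnett_vs_control(
    groups: Sequence[np.ndarray],
    control: np.ndarray,
    alpha: float = 0.05,
    n_draws: int = 100_000,
    seed: int = 0,
    mc: Optional[MonteCarloDunnett] = None,
) -> pd.DataFrame:
    """Welch t tests of each group against the control, Dunnett-adjusted.

    Returns a DataFrame with columns ``t``, ``p_unadjusted`` (Welch-
    Satterthwaite) , ``p_adjusted`` and ``significant`` (at ``alpha``).
    Group sizes must be equal (replicate spots of one array); a shared
    ``mc`` null can be passed to amortize the simulation.
    """
    garr = [np.asarray(g, dtype=float) for g in groups]
    ctrl = np.asarray(control, dtype=float)
    if any(g.size < 2 for g in garr) or ctrl.size < 2:
        raise ValueError("each group and the control need at least 2 replicates")
    sizes = {g.size for g in garr}
    if len(sizes) != 1:
        raise ValueError("groups must share a replicate count")
    (gsize,) = sizes
    if mc is None:
        mc = MonteCarloDunnett(
            n_groups=len(garr),
            group_size=gsize,
            control_size=ctrl.size,
            n_draws=n_draws,
            seed=seed,
        )
    tvals = np.array([welch_t(g, ctrl) for g in garr])
    p_unadj = np.array(
        [stats.ttest_ind(g, ctrl, equal_var=False).pvalue for g in garr]
    )
    p_adj = mc.adjust(tvals)
    return pd.DataFrame(
        {
            "t": tvals,
            "p_unadjusted": p_unadj,
            "p_adjusted": p_adj,
            "significant": p_adj < alpha,
        }
    )


def analyze_array(
    image: np.ndarray,
    layout: ArrayLayout,
    alpha: float = 0.05,
    n_draws: int = 100_000,
    seed: int = 0,
    mc: Optional[MonteCarloDunnett] = None,
) -> pd.DataFrame:
    """Full per-glycan analysis of one array image.

    Quantifies and normalizes all spots, then reports per glycan the mean
    normalized signal, the detection call (corrected mean > 2x mean local
    background SD) and the Dunnett-adjusted Welch p-value of a one-sided
    increase versus the pooled negative controls.  ``hit`` requires both a
    detection and significance with a positive shift.
    """
    spots = quantify_array(image, layout)
    controls = spots.loc[spots.is_control, "normalized"].to_numpy()
    per_glycan = []
    groups = []
    for name in layout.glycans:
        sel = spots[(spots.glycan == name) & (~spots.is_control)]
        groups.append(sel["normalized"].to_numpy())
        per_glycan.append(
            (
                name,
                float(sel["normalized"].mean()),
                float(sel["corrected"].mean()),
                float(sel["background_sd"].mean()),
            )
        )
    tests = dunnett_vs_control(
        groups, controls, alpha=alpha, n_draws=n_draws, seed=seed, mc=mc
    )
    out = pd.DataFrame(
        per_glycan, columns=["glycan", "mean_normalized", "mean_corrected", "mean_background_sd"]
    )
    out["detected"] = [
        detection_call(cm, sd)
        for cm, sd in zip(out["mean_corrected"], out["mean_background_sd"])
    ]
    out["t"] = tests["t"].to_numpy()
    out["p_adjusted"] = tests["p_adjusted"].to_numpy()
    out["significant"] = (out["t"] > 0) & (out["p_adjusted"] < alpha)
    out["hit"] = out["detected"] & out["significant"]
    return out
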
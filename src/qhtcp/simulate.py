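"""Seeded synthetic screens with known ground truth.

The generator emulates the statistical structure of the oligomycin
chemical-genomic screen so every pipeline stage can be verified at desk
scale:

* each strain grows logistically with strain-specific (K, r, L);
* the reference strain's L increases with oligomycin dose along a
  monotone quadratic RD(D) = L_ref0 + a*D + b*D^2;
* a gene deletion shifts L by a dose-independent main effect K0 and by a
  planted quadratic interaction B*D + C*D^2;
* strong enhancers are censored (no measurable growth) at high doses via
  a horizon rule applied to the noise-free composed L, which makes
  censoring monotone in dose;
* the reference is replicated (768 cultures per dose by default) and
  overlapping-ORF deletion pairs share their planted effect up to small
  independent noise.

All outputs are bit-for-bit reproducible from (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .growth import TimeSeries, logistic
from .interaction import DoseResponse
from .plates import PlateGrid, PlateImageStack

DEFAULT_DOSES: tuple[float, ...] = (0.0, 0.05, 0.10, 0.15, 0.20, 0.25)


@dataclass(frozen=True)
class ScreenConfig:
    """Study conditions of a synthetic screen.

    Doses are the oligomycin ladder in ug/mL; L-scale quantities are
    hours.  Planted interaction magnitudes are drawn uniformly from
    ``enhancer_int_range`` / ``suppressor_int_range`` (the values an
    analysis would measure at the full top dose), split between linear
    and quadratic dose terms by a random curvature fraction.
    """

    n_genes: int = 500
    doses: tuple[float, ...] = DEFAULT_DOSES
    n_reference_replicates: int = 768
    frac_enhancers: float = 0.10
    frac_suppressors: float = 0.10
    # reference dose response RD(D) = L_ref0 + a*D + b*D^2
    L_ref0: float = 30.0
    dose_linear: float = 20.0  # a, h·mL/ug
    dose_quadratic: float = 100.0  # b, h·(mL/ug)^2
    # strain-level logistic parameters at dose 0
    K_range: tuple[float, float] = (80.0, 120.0)
    r_range: tuple[float, float] = (0.3, 0.5)
    baseline: float = 5.0
    # planted effect distributions
    K0_sd: float = 2.0
    enhancer_int_range: tuple[float, float] = (15.0, 40.0)
    suppressor_int_range: tuple[float, float] = (-40.0, -24.0)
    curvature_fraction: float = 0.3  # |C|·D_max^2 <= this fraction of |INT|
    # noise and censoring
    intensity_noise_sd: float = 2.0
    L_noise_sd: float = 0.5
    censor_horizon: float = 70.0  # composed L above this -> no growth
    # observation window
    times: tuple[float, ...] = tuple(float(t) for t in range(0, 97, 4))
    # overlapping-ORF pairs
    n_overlap_pairs: int = 30
    overlap_pair_noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frac_enhancers + self.frac_suppressors > 1.0:
            raise ValueError("enhancer + suppressor fractions must not exceed 1")
        if self.doses[0] != 0.0:
            raise ValueError("dose ladder must start at 0")
        if self.censor_horizon <= self.L_ref0:
            raise ValueError(
                "censor horizon must exceed the reference L at dose 0"
            )

    def reference_L(self, dose: float) -> float:
        return (
            self.L_ref0
            + self.dose_linear * dose
            + self.dose_quadratic * dose * dose
        )


@dataclass(frozen=True)
class SyntheticScreen:
    """A generated screen: per-strain dose responses (true L values, with
    NaN at censored doses), per-dose reference replicate L values, the
    rendered time series, and the ground-truth table."""

    config: ScreenConfig
    dose_responses: dict[str, DoseResponse]
    reference_L_by_dose: dict[float, np.ndarray]
    series: dict[tuple[str, float], TimeSeries]
    reference_series: dict[tuple[int, float], TimeSeries]
    truth: pd.DataFrame
    overlap_pairs: pd.DataFrame


def _planted_effects(cfg: ScreenConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw per-gene planted (K0, B, C, class); overlap-pair members are
    appended after the regular genes with shared effects."""
    n_enh = int(round(cfg.n_genes * cfg.frac_enhancers))
    n_sup = int(round(cfg.n_genes * cfg.frac_suppressors))
    n_null = cfg.n_genes - n_enh - n_sup
    d_top = cfg.doses[-1]

    def draw_bc(target_int: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        u = rng.uniform(-cfg.curvature_fraction, cfg.curvature_fraction, target_int.size)
        C = u * target_int / (d_top * d_top)
        B = (target_int - C * d_top * d_top) / d_top
        return B, C

    classes = (
        ["deletion_enhancer"] * n_enh
        + ["deletion_suppressor"] * n_sup
        + ["none"] * n_null
    )
    target = np.concatenate([
        rng.uniform(*cfg.enhancer_int_range, n_enh),
        rng.uniform(*cfg.suppressor_int_range, n_sup),
        np.zeros(n_null),
    ])
    B = np.zeros(cfg.n_genes)
    C = np.zeros(cfg.n_genes)
    planted = target != 0.0
    B[planted], C[planted] = draw_bc(target[planted])
    K0 = rng.normal(0.0, cfg.K0_sd, cfg.n_genes)
    genes = [f"ORF{i:04d}" for i in range(cfg.n_genes)]
    order = rng.permutation(cfg.n_genes)
    return pd.DataFrame(
        {
            "gene": genes,
            "planted_class": np.array(classes, dtype=object)[order],
            "planted_K0": K0,
            "planted_B": B[order],
            "planted_C": C[order],
        }
    )


def _overlap_effects(cfg: ScreenConfig, rng: np.random.Generator) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Overlapping-ORF pairs: both members inherit a shared planted effect
    plus independent jitter on K0 (their deleted regions overlap, so their
    interactions should agree)."""
    d_top = cfg.doses[-1]
    rows, pairs = [], []
    for i in range(cfg.n_overlap_pairs):
        shared_int = rng.normal(0.0, 15.0)
        u = rng.uniform(-cfg.curvature_fraction, cfg.curvature_fraction)
        C = u * shared_int / (d_top * d_top)
        B = (shared_int - C * d_top * d_top) / d_top
        k0 = rng.normal(0.0, cfg.K0_sd)
        ida, idb = f"OVL{i:03d}A", f"OVL{i:03d}B"
        for gid in (ida, idb):
            rows.append(
                {
                    "gene": gid,
                    "planted_class": "overlap_pair",
                    "planted_K0": k0 + rng.normal(0.0, 0.5),
                    "planted_B": B + rng.normal(0.0, cfg.overlap_pair_noise_sd / d_top),
                    "planted_C": C,
                }
            )
        pairs.append({"orf_id": ida, "overlap_id": idb, "shared_INT": shared_int})
    return pd.DataFrame(rows), pd.DataFrame(pairs)


def _compose_truth(cfg: ScreenConfig, effects: pd.DataFrame) -> pd.DataFrame:
    """Attach noise-free composed L per dose, the censoring tier, and the
    implied INT at the censored top dose."""
    doses = np.asarray(cfg.doses)
    ref = np.array([cfg.reference_L(d) for d in doses])
    out = effects.copy()
    tiers, d_max, implied = [], [], []
    for _, row in effects.iterrows():
        L_true = (
            ref
            + row["planted_K0"]
            + row["planted_B"] * doses
            + row["planted_C"] * doses * doses
        )
        censored = L_true > cfg.censor_horizon
        # censoring is monotone: once a dose censors, all higher doses do
        if censored.any():
            censored[np.argmax(censored):] = True
        if censored[0]:
            raise ValueError(
                f"{row['gene']}: composed L at dose 0 exceeds the horizon"
            )
        grown = doses[~censored]
        tiers.append(int(censored.sum()))
        dm = float(grown[-1])
        d_max.append(dm)
        implied.append(float(row["planted_B"] * dm + row["planted_C"] * dm * dm))
    out["planted_tier"] = tiers
    out["planted_D_max"] = d_max
    out["planted_INT"] = implied
    return out


def generate_dose_responses(cfg: ScreenConfig) -> SyntheticScreen:
    """Generate the screen at the L level (no time-series rendering).

    Returns a :class:`SyntheticScreen` whose ``series`` dictionaries are
    empty; use :func:`generate_screen` for the full image-free pipeline
    input including rendered intensity series.
    """
    rng = np.random.default_rng(cfg.seed)
    effects = _planted_effects(cfg, rng)
    overlap, pairs = _overlap_effects(cfg, rng)
    effects = pd.concat([effects, overlap], ignore_index=True)
    truth = _compose_truth(cfg, effects)

    doses = np.asarray(cfg.doses)
    ref_curve = np.array([cfg.reference_L(d) for d in doses])

    reference_L_by_dose = {
        float(d): ref_curve[i] + rng.normal(0.0, cfg.L_noise_sd, cfg.n_reference_replicates)
        for i, d in enumerate(doses)
    }

    dose_responses: dict[str, DoseResponse] = {}
    for _, row in truth.iterrows():
        L_true = (
            ref_curve
            + row["planted_K0"]
            + row["planted_B"] * doses
            + row["planted_C"] * doses * doses
        )
        grown = doses <= row["planted_D_max"]
        L_obs = np.where(grown, L_true + rng.normal(0.0, cfg.L_noise_sd, doses.size), np.nan)
        dose_responses[row["gene"]] = DoseResponse(
            row["gene"], doses.copy(), L_obs, grown.copy()
        )
    return SyntheticScreen(
        cfg, dose_responses, reference_L_by_dose, {}, {}, truth, pairs
    )


def _render_series(
    culture_id: str,
    K: float,
    r: float,
    L: float,
    cfg: ScreenConfig,
    rng: np.random.Generator,
    grew: bool,
) -> TimeSeries:
    t = np.asarray(cfg.times)
    if grew:
        y = logistic(t, cfg.baseline, K, r, L)
    else:
        y = np.full(t.size, cfg.baseline)
    if cfg.intensity_noise_sd > 0:
        y = y + rng.normal(0.0, cfg.intensity_noise_sd, t.size)
    return TimeSeries(culture_id, t.copy(), y)


def generate_screen(cfg: ScreenConfig) -> SyntheticScreen:
    """Generate the full screen: dose responses plus rendered logistic
    intensity time series for every culture (censored cultures render as
    flat-at-baseline noise so the no-growth detector path is exercised)."""
    screen = generate_dose_responses(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    series: dict[tuple[str, float], TimeSeries] = {}
    ref_series: dict[tuple[int, float], TimeSeries] = {}

    for gene, dr in screen.dose_responses.items():
        K = rng.uniform(*cfg.K_range)
        r = rng.uniform(*cfg.r_range)
        for j, dose in enumerate(dr.doses):
            series[(gene, float(dose))] = _render_series(
                f"{gene}@{dose:g}", K, r, float(dr.L_values[j]) if dr.grew[j] else np.nan,
                cfg, rng, bool(dr.grew[j]),
            )
    for dose, Ls in screen.reference_L_by_dose.items():
        for i, Lval in enumerate(Ls):
            K = rng.uniform(*cfg.K_range)
            r = rng.uniform(*cfg.r_range)
            ref_series[(i, float(dose))] = _render_series(
                f"REF{i:04d}@{dose:g}", K, r, float(Lval), cfg, rng, True
            )
    return replace(screen, series=series, reference_series=ref_series)


def generate_profiles(
    n_per_cluster: Sequence[int],
    centers: np.ndarray,
    sd: float,
    seed: int,
    columns: Sequence[str] | None = None,
):
    """Gaussian interaction profiles around planted cluster centers.

    Returns (profiles, labels); labels index into ``centers`` and serve as
    ground truth for adjusted-Rand-index checks.
    """
    from .clustering import PROFILE_COLUMNS, InteractionProfile

    if columns is None:
        columns = PROFILE_COLUMNS
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    if centers.shape[1] != len(columns):
        raise ValueError(
            f"centers must have {len(columns)} columns, got {centers.shape[1]}"
        )
    if len(n_per_cluster) != centers.shape[0]:
        raise ValueError("one size per center required")
    if sd <= 0:
        raise ValueError("sd must be positive")
    rng = np.random.default_rng(seed)
    profiles, labels = [], []
    idx = 0
    for label, (n, center) in enumerate(zip(n_per_cluster, centers)):
        for _ in range(n):
            vals = center + rng.normal(0.0, sd, center.size)
            profiles.append(
                InteractionProfile(f"G{idx:04d}", vals, np.zeros(center.size, dtype=bool))
            )
            labels.append(label)
            idx += 1
    return profiles, np.array(labels, dtype=int)


def render_plate_images(
    cultures: Sequence[TimeSeries],
    cfg: ScreenConfig,
    grid: PlateGrid = PlateGrid(),
    background_level: float = 10.0,
    pixel_noise_sd: float = 0.0,
    spot_sigma: float | None = None,
    seed: int = 0,
) -> PlateImageStack:
    """Render cultures onto a synthetic plate-image stack.

    Cultures fill the grid row-major; each spot is a 2-D Gaussian whose
    integrated amplitude tracks the culture's background-subtracted
    intensity trajectory on a flat background.  All cultures must share
    the same observation times.
    """
    if len(cultures) > grid.rows * grid.cols:
        raise ValueError(
            f"{len(cultures)} cultures exceed the {grid.rows}x{grid.cols} grid"
        )
    times = cultures[0].times if cultures else np.asarray(cfg.times)
    for c in cultures:
        if not np.array_equal(c.times, times):
            raise ValueError("all cultures must share the same frame times")
    if spot_sigma is None:
        spot_sigma = grid.pitch / 8.0
    h = int(round(2 * grid.origin_row + (grid.rows - 1) * grid.pitch))
    w = int(round(2 * grid.origin_col + (grid.cols - 1) * grid.pitch))
    yy, xx = np.mgrid[0:h, 0:w]
    rng = np.random.default_rng(seed)
    frames = np.full((times.size, h, w), float(background_level))
    for idx, culture in enumerate(cultures):
        row, col = divmod(idx, grid.cols)
        cr, cc = grid.center(row, col)
        kernel = np.exp(
            -((yy - cr) ** 2 + (xx - cc) ** 2) / (2.0 * spot_sigma**2)
        )
        kernel /= kernel.sum()
        for f, amplitude in enumerate(culture.intensities):
            frames[f] += max(float(amplitude), 0.0) * kernel
    if pixel_noise_sd > 0:
        frames += rng.normal(0.0, pixel_noise_sd, frames.shape)
        frames = np.clip(frames, 0.0, None)
    return PlateImageStack(frames, times, grid)
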
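"""Dose-response gene-interaction scoring.

A gene interaction is the departure of a double mutant's oligomycin dose
response — summarised by the logistic parameter L per dose — from the
replicated single-mutant reference, after removing the drug's dose effect
and the deletion's drug-independent growth effect:

1. reference central tendency per dose:  RD_i
2. remove the dose effect:               K_i = Y_i - RD_i
3. remove the knockout effect:           L_i = K_i - K_0   (so L_0 = 0)
4. quadratic fit over doses:             L_i = A + B*D_i + C*D_i^2
5. interaction value at the top dose:    INT = A + B*D_max + C*D_max^2

where D_max is the highest dose with measurable growth.  Strains failing
to grow at one or more doses are additionally ranked in tiers: the more
doses without growth, the stronger the deletion enhancer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

DELETION_ENHANCER = "deletion_enhancer"
DELETION_SUPPRESSOR = "deletion_suppressor"
NO_INTERACTION = "none"


class DoseLadderError(ValueError):
    """Raised when a dose ladder violates its invariants."""


@dataclass(frozen=True)
class DoseResponse:
    """Per-strain fitted L across the oligomycin ladder.

    ``L_values`` holds NaN exactly where ``grew`` is False.
    """

    strain_id: str
    doses: np.ndarray
    L_values: np.ndarray
    grew: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.doses, dtype=float)
        L = np.asarray(self.L_values, dtype=float)
        g = np.asarray(self.grew, dtype=bool)
        object.__setattr__(self, "doses", d)
        object.__setattr__(self, "L_values", L)
        object.__setattr__(self, "grew", g)
        if not (d.size == L.size == g.size):
            raise DoseLadderError(f"{self.strain_id}: ragged dose ladder")
        if np.any(np.diff(d) <= 0):
            raise DoseLadderError(f"{self.strain_id}: doses must strictly increase")
        if d[0] != 0.0:
            raise DoseLadderError(f"{self.strain_id}: dose ladder must start at 0")
        if np.any(np.isnan(L) == g):
            raise DoseLadderError(
                f"{self.strain_id}: L must be present exactly where grew is True"
            )


@dataclass(frozen=True)
class ReferenceModel:
    """Per-dose central tendency and central-95% band of the replicated
    single-mutant reference."""

    doses: np.ndarray
    central: np.ndarray
    band_low: np.ndarray
    band_high: np.ndarray
    n_replicates: np.ndarray


@dataclass(frozen=True)
class Thresholds:
    """Interaction-value cuts for enhancer / suppressor calls (strict
    inequalities).  Defaults are the misfolded-allele screen's cuts; the
    wild-type screen uses (10, -12)."""

    enhancer_cut: float = 10.0
    suppressor_cut: float = -16.0

    def __post_init__(self) -> None:
        if not (self.enhancer_cut > 0 > self.suppressor_cut):
            raise ValueError("require enhancer_cut > 0 > suppressor_cut")


WILDTYPE_THRESHOLDS = Thresholds(10.0, -12.0)


@dataclass(frozen=True)
class QCConfig:
    """Cuts behind the automated high-confidence flags (all in hours or
    hours per dose unit)."""

    k0_cut: float = 10.0  # |K0| above this is a large zero-dose effect
    quad_r2_cut: float = 0.8  # quadratic fit quality below this is poor
    plateau_slope_cut: float = 5.0  # |dL/dD| at D_max below this flags a plateau
    weak_int_cut: float = 10.0  # |INT| below this is a weak effect


@dataclass(frozen=True)
class InteractionResult:
    """Scored interaction for one strain.

    ``INT`` (and A, B, C) are NaN when fewer than three doses grew; the
    strain is then still rankable through ``tier``.  ``L_adj`` is the
    dose-effect- and knockout-effect-removed response (NaN where censored).
    """

    strain_id: str
    K0: float
    A: float
    B: float
    C: float
    INT: float
    D_max_scored: float
    tier: int
    quad_r2: float
    L_adj: np.ndarray
    interaction_class: str = NO_INTERACTION
    qc_flags: frozenset[str] = field(default_factory=frozenset)


def build_reference(
    replicate_L_by_dose: Mapping[float, Sequence[float]],
    stat: str = "median",
) -> ReferenceModel:
    """Summarise the replicated reference strain per dose.

    Censored (non-grown, NaN) replicates are dropped per dose; the central
    tendency is the median (the default null model for the drug effect) or
    the mean, and the band holds the empirical 2.5/97.5 percentiles.
    """
    if stat not in ("median", "mean"):
        raise ValueError(f"unknown central-tendency stat {stat!r}")
    doses = np.array(sorted(replicate_L_by_dose), dtype=float)
    central, lo, hi, counts = [], [], [], []
    for dose in doses:
        vals = np.asarray(replicate_L_by_dose[dose], dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size < 2:
            raise DoseLadderError(
                f"dose {dose}: need >= 2 grown reference replicates, got {vals.size}"
            )
        central.append(np.median(vals) if stat == "median" else np.mean(vals))
        lo.append(np.percentile(vals, 2.5))
        hi.append(np.percentile(vals, 97.5))
        counts.append(vals.size)
    return ReferenceModel(
        doses, np.array(central), np.array(lo), np.array(hi),
        np.array(counts, dtype=int),
    )


def score_interaction(dr: DoseResponse, ref: ReferenceModel) -> InteractionResult:
    """Apply the five scoring steps to one strain's dose response."""
    if dr.doses.size != ref.doses.size or not np.allclose(dr.doses, ref.doses):
        raise DoseLadderError(
            f"{dr.strain_id}: dose ladder differs from the reference model"
        )
    if not dr.grew[0]:
        raise DoseLadderError(
            f"{dr.strain_id}: no growth at dose 0 — interaction undefined"
        )

    K = dr.L_values - ref.central  # step 2, NaN where censored
    K0 = float(K[0])  # step 3: knockout main effect
    L_adj = K - K0  # L_adj[0] == 0 exactly
    tier = int(np.count_nonzero(~dr.grew))
    grown = dr.grew

    if np.count_nonzero(grown) < 3:
        return InteractionResult(
            dr.strain_id, K0, math.nan, math.nan, math.nan, math.nan,
            math.nan, tier, math.nan, L_adj,
        )

    d = dr.doses[grown]
    y = L_adj[grown]
    # step 4: unweighted least-squares quadratic (free intercept)
    C, B, A = (float(v) for v in np.polyfit(d, y, 2))
    yhat = A + B * d + C * d * d
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    quad_r2 = 1.0 if ss_tot == 0.0 and ss_res < 1e-18 else (
        1.0 - ss_res / ss_tot if ss_tot > 0.0 else -math.inf
    )
    d_max = float(d[-1])
    INT = A + B * d_max + C * d_max * d_max  # step 5
    return InteractionResult(
        dr.strain_id, K0, A, B, C, float(INT), d_max, tier, quad_r2, L_adj
    )


def classify(res: InteractionResult, th: Thresholds = Thresholds()) -> str:
    """Call deletion enhancer / suppressor / none (strict inequalities).

    Strains with no scoreable INT but one or more no-growth doses are
    enhancers by tier.
    """
    if math.isnan(res.INT):
        return DELETION_ENHANCER if res.tier > 0 else NO_INTERACTION
    if res.INT > th.enhancer_cut:
        return DELETION_ENHANCER
    if res.INT < th.suppressor_cut:
        return DELETION_SUPPRESSOR
    return NO_INTERACTION


def classify_all(
    results: Iterable[InteractionResult], th: Thresholds = Thresholds()
) -> list[InteractionResult]:
    """Return results with their interaction_class filled in."""
    return [replace(r, interaction_class=classify(r, th)) for r in results]


def rank_interactions(results: Iterable[InteractionResult]) -> list[InteractionResult]:
    """Order by tier (descending), then INT (descending, unscoreable
    no-growth strains first within a tier), then strain id."""

    def key(r: InteractionResult):
        int_key = math.inf if math.isnan(r.INT) else r.INT
        return (-r.tier, -int_key, r.strain_id)

    return sorted(results, key=key)


def gene_drug_score(
    deletion_L: float,
    deletion_control_L: float,
    reference_L: float,
    reference_control_L: float,
) -> float:
    """Single-condition interaction: deletion-vs-reference L difference on
    the drug medium, adjusted for the same difference on the control
    medium.  NaN inputs (no growth) propagate to a NaN score."""
    return (deletion_L - reference_L) - (deletion_control_L - reference_control_L)


def overlap_orf_correlation(
    pairs: Sequence[tuple[InteractionResult, InteractionResult]],
) -> tuple[float, pd.DataFrame]:
    """Reproducibility diagnostic over deletion pairs with overlapping ORFs.

    Because overlapping deletions remove shared sequence, their interaction
    scores should correlate; returns the Pearson r over pairs where both
    members scored, plus the paired scatter table.
    """
    table = pd.DataFrame(
        {
            "orf_id": [a.strain_id for a, _ in pairs],
            "overlap_id": [b.strain_id for _, b in pairs],
            "orf_INT": [a.INT for a, _ in pairs],
            "overlap_INT": [b.INT for _, b in pairs],
        }
    )
    complete = table.dropna(subset=["orf_INT", "overlap_INT"])
    if len(complete) < 3:
        raise ValueError(
            f"need >= 3 pairs with scored INT, got {len(complete)}"
        )
    r, _ = stats.pearsonr(complete["orf_INT"], complete["overlap_INT"])
    return float(r), table


def qc_flags(
    res: InteractionResult,
    companion: InteractionResult | None = None,
    companion_thresholds: Thresholds = WILDTYPE_THRESHOLDS,
    cfg: QCConfig = QCConfig(),
) -> frozenset[str]:
    """Automated high-confidence screening flags.

    large_zero_dose_effect: the deletion alone strongly changes growth,
        confounding the drug response.
    wildtype_context_interaction: the same deletion interacts in the
        companion (wild-type transporter) screen, so the effect is not
        allele specific.
    poor_quadratic_fit: the dose trend is not well described by the
        quadratic model.
    plateau_response: |dL/dD| at D_max is small while |INT| is large — the
        response saturated rather than trending.
    weak_effect: |INT| below the weak-effect cut.

    High-confidence interactions carry an empty flag set (and a class other
    than none).
    """
    flags: set[str] = set()
    if abs(res.K0) > cfg.k0_cut:
        flags.add("large_zero_dose_effect")
    if companion is not None:
        companion_hit = (
            classify(companion, companion_thresholds) != NO_INTERACTION
        )
        if companion_hit:
            flags.add("wildtype_context_interaction")
    if not math.isnan(res.quad_r2) and res.quad_r2 < cfg.quad_r2_cut:
        flags.add("poor_quadratic_fit")
    if not math.isnan(res.INT):
        slope_at_max = res.B + 2.0 * res.C * res.D_max_scored
        if abs(slope_at_max) < cfg.plateau_slope_cut and abs(res.INT) >= cfg.weak_int_cut:
            flags.add("plateau_response")
        if abs(res.INT) < cfg.weak_int_cut:
            flags.add("weak_effect")
    return frozenset(flags)


def is_high_confidence(res: InteractionResult) -> bool:
    return not res.qc_flags and res.interaction_class != NO_INTERACTION
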
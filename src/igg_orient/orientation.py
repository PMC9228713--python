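"""Orientation inference from PC scores and surface density.

Three steps turn orientation-component scores into an orientation story:

1. **Regime segmentation.**  Samples sorted by surface density Γ are
   split into three contiguous groups (flat-on, side-on, vertical) by
   exhaustive search over breakpoint pairs, choosing the split that
   maximises the one-way ANOVA F statistic of the orientation scores.
   The split is accepted only if the omnibus ANOVA and all pairwise
   Welch tests are significant.

2. **Score calibration.**  PC scores are assumed linear in the areal
   fraction f_Fc of exposed Fc domain.  The flat-on and side-on group
   mean scores are anchored to the molecular-dynamics values
   f_Fc = 0.28 (flat-on) and 0.34 (side-on), defining an affine map
   score → f_Fc.

3. **Vertical-regime unmixing.**  A vertical layer is a mixture of
   head-on (Fc up, f_Fc = h) and tail-on (Fc down, f_Fc = t) molecules.
   The lever rule p = (f − t)/(h − t) resolves the head-on fraction from
   the calibrated f_Fc of the vertical group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "OrientationCalibration",
    "MixtureEndmembers",
    "RegimeSegmentation",
    "SampleRecord",
    "FFC_FLAT_ON",
    "FFC_SIDE_ON",
    "calibrate",
    "score_to_ffc",
    "invert_mixture",
    "forward_mixture",
    "fit_endmembers",
    "anova_oneway",
    "segment_regimes",
]

# Areal fractions of exposed Fc domain for flat-on and side-on IgG,
# from published molecular-dynamics simulation of surface-bound IgG.
FFC_FLAT_ON = 0.28
FFC_SIDE_ON = 0.34

REGIME_LABELS = ("flat_on", "side_on", "vertical")


@dataclass(frozen=True)
class OrientationCalibration:
    """Affine map f_Fc = a·s + b anchored at the flat-on/side-on levels."""

    s_flat: float
    s_side: float
    f_flat: float = FFC_FLAT_ON
    f_side: float = FFC_SIDE_ON

    def __post_init__(self) -> None:
        if self.s_flat == self.s_side:
            raise ValueError("anchor scores must differ")

    @property
    def slope(self) -> float:
        return (self.f_side - self.f_flat) / (self.s_side - self.s_flat)

    @property
    def intercept(self) -> float:
        return self.f_flat - self.slope * self.s_flat


def calibrate(
    s_flat: float,
    s_side: float,
    f_flat: float = FFC_FLAT_ON,
    f_side: float = FFC_SIDE_ON,
) -> OrientationCalibration:
    """Two-point calibration of the score → f_Fc map."""
    return OrientationCalibration(
        s_flat=float(s_flat), s_side=float(s_side), f_flat=f_flat, f_side=f_side
    )


def score_to_ffc(cal: OrientationCalibration, s) -> float | np.ndarray:
    """Apply the calibration.  Out-of-[0,1] values are returned untouched —
    they are diagnostics of a miscalibration, never clamped."""
    out = cal.slope * np.asarray(s, dtype=float) + cal.intercept
    return float(out) if np.isscalar(s) else out


@dataclass(frozen=True)
class MixtureEndmembers:
    """f_Fc of the pure vertical endmembers: head-on ``h`` > tail-on ``t``.

    Head-on molecules stand on the Fab arms with the Fc trunk exposed
    (large f_Fc); tail-on molecules stand on the Fc with the arms exposed
    (small f_Fc).  Defaults h = 0.5, t = 0.0.
    """

    h: float = 0.5
    t: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.t < self.h <= 1.0):
            raise ValueError(f"need 0 <= t < h <= 1, got t={self.t}, h={self.h}")


def invert_mixture(f: float, em: MixtureEndmembers = MixtureEndmembers()) -> float:
    """Lever rule: head-on fraction p = (f − t)/(h − t)."""
    if not em.t <= f <= em.h:
        raise ValueError(
            f"f_Fc={f} outside the mixture gamut [t={em.t}, h={em.h}]: "
            "no head-on/tail-on mixture can produce it"
        )
    return (f - em.t) / (em.h - em.t)


def forward_mixture(p: float, em: MixtureEndmembers = MixtureEndmembers()) -> float:
    """f_Fc of a mixture with head-on fraction ``p``: p·h + (1−p)·t."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"head-on fraction must be in [0,1], got {p}")
    return p * em.h + (1.0 - p) * em.t


def fit_endmembers(
    pairs: list[tuple[float, float]],
) -> MixtureEndmembers:
    """Least-squares endmembers from (head_fraction, f_Fc) pairs, t >= 0.

    Solves f ≈ p·h + (1−p)·t over the supplied pairs; if the
    unconstrained tail-on endmember comes out negative it is pinned at 0
    and h refitted.
    """
    if len(pairs) < 2:
        raise ValueError("need at least two (p, f) pairs")
    P = np.array([[p, 1.0 - p] for p, _ in pairs])
    f = np.array([x for _, x in pairs])
    (h, t), *_ = np.linalg.lstsq(P, f, rcond=None)
    if t < 0:
        t = 0.0
        h = float(np.sum(P[:, 0] * f) / np.sum(P[:, 0] ** 2))
    if not t < h:
        raise ValueError(f"degenerate endmember fit: h={h}, t={t}")
    return MixtureEndmembers(h=float(h), t=float(t))


def anova_oneway(groups: list[np.ndarray]) -> tuple[float, float]:
    """One-way fixed-effects ANOVA: F with (k−1, N−k) df and its p value.

    Degenerate case: zero within-group variance with unequal group means
    gives F = +inf, p = 0 (a perfect step), rather than NaN.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for g in arrays:
        if len(g) < 2:
            raise ValueError("every group needs at least 2 values")
    N = sum(len(g) for g in arrays)
    k = len(arrays)
    grand = np.concatenate(arrays).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in arrays)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in arrays)
    df_b, df_w = k - 1, N - k
    if ss_within == 0.0:
        if ss_between == 0.0:
            return 0.0, 1.0
        return float("inf"), 0.0
    F = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(F, df_b, df_w))
    return float(F), p


@dataclass
class SampleRecord:
    """Per-sample result row of the orientation analysis."""

    sample_id: str
    gamma: float            # mg/m^2
    d_nm: float
    score: float            # orientation-PC score (sign convention applied)
    f_fc: float | None = None
    regime: str | None = None
    head_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError(f"negative surface density for {self.sample_id!r}")


@dataclass
class RegimeSegmentation:
    """Result of the three-group Γ segmentation."""

    significant: bool
    boundaries: tuple[float, float] | None   # (Gamma_1, Gamma_2) in mg/m^2
    assignment: list[str]                    # regime label per (Γ-sorted) sample
    group_means: dict[str, float]
    f_statistic: float
    p_value: float
    pairwise_p: dict[str, float] = field(default_factory=dict)
    breakpoints: tuple[int, int] | None = None  # indices into the sorted sequence
    best_boundaries: tuple[float, float] | None = None  # max-F split, even if
                                                        # not significant


def segment_regimes(
    records: list[SampleRecord],
    alpha: float = 0.05,
    min_group_size: int = 2,
) -> RegimeSegmentation:
    """Split a Γ-ordered score series into flat-on / side-on / vertical.

    Exhaustive search over ordered breakpoint pairs (i < j): group 1 is
    samples [0, i), group 2 [i, j), group 3 [j, n).  The pair maximising
    the one-way ANOVA F of the orientation scores wins; boundaries are
    reported as midpoints between the adjacent Γ values.  The
    segmentation is *significant* only if the omnibus p < alpha and the
    Welch tests of both regime *transitions* (flat-on vs side-on and
    side-on vs vertical) pass a Bonferroni-corrected alpha/2.  The
    flat-on vs vertical contrast is reported but not required: a mixed
    head-on/tail-on vertical layer can legitimately reproduce the
    flat-on composition, so those two score levels may coincide.
    """
    if len(records) < 3 * min_group_size:
        raise ValueError(
            f"need at least {3 * min_group_size} samples, got {len(records)}"
        )
    order = np.argsort([r.gamma for r in records], kind="stable")
    recs = [records[i] for i in order]
    gammas = np.array([r.gamma for r in recs])
    scores = np.array([r.score for r in recs])
    if len(np.unique(gammas)) < 3:
        raise ValueError("need at least 3 distinct surface-density values")
    n = len(recs)

    best: tuple[float, int, int] | None = None
    for i in range(min_group_size, n - 2 * min_group_size + 1):
        for j in range(i + min_group_size, n - min_group_size + 1):
            F, _ = anova_oneway([scores[:i], scores[i:j], scores[j:]])
            if best is None or F > best[0]:
                best = (F, i, j)
    assert best is not None
    F, i, j = best
    _, p = anova_oneway([scores[:i], scores[i:j], scores[j:]])

    groups = {
        "flat_on": scores[:i],
        "side_on": scores[i:j],
        "vertical": scores[j:],
    }
    group_means = {k: float(v.mean()) for k, v in groups.items()}

    transitions = ("flat_on|side_on", "side_on|vertical")
    pair_alpha = alpha / len(transitions)
    pairwise_p: dict[str, float] = {}
    for pair in ("flat_on|side_on", "flat_on|vertical", "side_on|vertical"):
        la, lb = pair.split("|")
        a, b = groups[la], groups[lb]
        if np.var(a) == 0 and np.var(b) == 0:
            pw = 0.0 if a.mean() != b.mean() else 1.0
        else:
            pw = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        pairwise_p[pair] = pw

    transitions_ok = all(pairwise_p[pair] < pair_alpha for pair in transitions)
    significant = (p < alpha) and transitions_ok
    best_boundaries = (
        float((gammas[i - 1] + gammas[i]) / 2.0),
        float((gammas[j - 1] + gammas[j]) / 2.0),
    )
    if significant:
        boundaries = best_boundaries
        assignment = ["flat_on"] * i + ["side_on"] * (j - i) + ["vertical"] * (n - j)
        for rec, lab in zip(recs, assignment):
            rec.regime = lab
    else:
        boundaries = None
        assignment = []

    return RegimeSegmentation(
        significant=significant,
        boundaries=boundaries,
        assignment=assignment,
        group_means=group_means,
        f_statistic=F,
        p_value=p,
        pairwise_p=pairwise_p,
        breakpoints=(i, j) if significant else None,
        best_boundaries=best_boundaries,
    )
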
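"""Expression-state classification of reactions (H / M / L).

Two routes turn expression measurements into the partition of reactions
into Highly/Over expressed (H), Lowly/Down expressed (L) and Medium
expressed/Invariant (M = R - H - L):

* **series route** - per-feature log2 expression measured across an
  ordered series of conditions (e.g. specific growth rates in 1/h).
  Each feature is regressed on the condition value and tested for a
  fold change across the condition range more extreme than a threshold
  T (a TREAT-style test); protein-level calls take precedence over
  gene-level calls; p-values are FDR-corrected and genes with q below
  the cut are called up or down by the sign of the regression slope.

* **fold-change route** - one log2 fold change per gene, thresholded at
  log2(1.5) = 0.5850 by default.

Gene states are projected onto reactions through the GPR Boolean rules
with the ternary coding up = +1, invariant = 0, down = -1 (AND = min,
OR = max): a reaction is H when its rule evaluates to +1, L when -1,
and M otherwise (including reactions with no rule).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .gpr import evaluate_ternary
from .network import MetabolicNetwork

__all__ = [
    "ExpressionSeries",
    "DifferentialCall",
    "GeneStateMap",
    "ReactionClassification",
    "preprocess",
    "threshold_regression_test",
    "merge_gene_protein",
    "estimate_fdr",
    "call_differential",
    "classify_by_fold_change",
    "map_to_reactions",
    "classify_series_route",
    "DEFAULT_FOLD_THRESHOLD",
    "DEFAULT_FDR_CUT",
    "DEFAULT_LOG2FC_CUTOFF",
]

DEFAULT_FOLD_THRESHOLD = 1.5
DEFAULT_FDR_CUT = 0.2
# log2(1.5) rounded as conventionally quoted for the 1.5-fold rule
DEFAULT_LOG2FC_CUTOFF = 0.5850

_STATE_CODE = {"up": 1, "invariant": 0, "down": -1}
_CODE_STATE = {1: "H", 0: "M", -1: "L"}

GeneStateMap = dict[str, str]  # gene id -> {"up", "down", "invariant"}
ReactionClassification = dict[str, str]  # reaction id -> {"H", "M", "L"}


class ExpressionTransformError(ValueError):
    """Raised when raw expression values cannot be log2-transformed."""


@dataclass
class ExpressionSeries:
    """Per-feature expression across an ordered list of conditions.

    ``values`` may contain NaN for missing measurements and are on log2
    scale once ``log2_scale`` is true (enforced by :func:`preprocess`).
    """

    feature_id: str
    kind: str  # "gene" or "protein"
    conditions: np.ndarray
    values: np.ndarray
    log2_scale: bool = True

    def __post_init__(self) -> None:
        self.conditions = np.asarray(self.conditions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.conditions.shape != self.values.shape:
            raise ValueError(
                f"{self.feature_id}: {len(self.values)} values for "
                f"{len(self.conditions)} conditions"
            )
        if self.kind not in ("gene", "protein"):
            raise ValueError(f"{self.feature_id}: kind must be gene or protein")

    @property
    def n_measured(self) -> int:
        return int(np.sum(~np.isnan(self.values)))


@dataclass
class DifferentialCall:
    feature_id: str
    p_value: float
    q_value: float | None = None
    sign: int = 0
    source: str = "none"  # "protein", "gene" or "none"


def preprocess(
    series: Iterable[ExpressionSeries],
    metabolic_genes: set[str],
    min_measurements: int = 4,
) -> tuple[list[ExpressionSeries], set[str]]:
    """Filter and normalise raw series.

    Features that do not map to a metabolic gene are dropped entirely;
    features with fewer than *min_measurements* non-missing values are
    routed to the invariant pool (returned as the second element);
    surviving raw-scale series are log2-transformed exactly once.
    Non-positive raw values cannot be log-transformed and raise.
    """
    kept: list[ExpressionSeries] = []
    invariant: set[str] = set()
    for s in series:
        if s.feature_id not in metabolic_genes:
            continue
        if s.n_measured < min_measurements:
            invariant.add(s.feature_id)
            continue
        if not s.log2_scale:
            with np.errstate(invalid="ignore"):
                bad = np.any(s.values[~np.isnan(s.values)] <= 0)
            if bad:
                raise ExpressionTransformError(
                    f"{s.feature_id}: non-positive raw value, cannot log2-transform"
                )
            s = replace(s, values=np.log2(s.values), log2_scale=True)
        kept.append(s)
    return kept, invariant


def threshold_regression_test(
    series: ExpressionSeries,
    fold_threshold: float = DEFAULT_FOLD_THRESHOLD,
    moderation: "VarianceModeration | None" = None,
) -> tuple[float, int]:
    """TREAT-style test of the fitted expression change against a threshold.

    Ordinary least squares regresses the log2 values on the condition
    value.  The tested effect is the fitted change over the full
    condition range, Delta = slope x (last condition - first condition),
    and the null hypothesis is |Delta| <= log2(fold_threshold).  The
    p-value is the sum of the two shifted tail probabilities

        p = P(t > (|Delta| - tau)/se) + P(t > (|Delta| + tau)/se),

    with tau = log2(fold_threshold), under the t distribution with the
    regression's residual degrees of freedom (capped at 1).  This is the
    threshold test used for moderated regression coefficients in
    differential-expression practice, computed here on unmoderated
    per-feature fits unless a :class:`VarianceModeration` is supplied.

    Returns ``(p_value, sign)`` where sign is the sign of the slope
    (0 for a flat fit or a degenerate condition design).
    """
    tau = math.log2(fold_threshold)
    mask = ~np.isnan(series.values)
    x = series.conditions[mask]
    y = series.values[mask]
    n = len(y)
    if n < 4:
        raise ValueError(
            f"{series.feature_id}: need >= 4 non-missing measurements, have {n}"
        )
    if len(np.unique(x)) < 2:
        # no direction estimable over a constant condition design
        return 1.0, 0
    df = n - 2
    if df < 3:
        warnings.warn(
            f"{series.feature_id}: only {df} residual degrees of freedom",
            stacklevel=2,
        )
    sxx = float(np.sum((x - x.mean()) ** 2))
    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    intercept = y.mean() - slope * x.mean()
    rss = float(np.sum((y - intercept - slope * x) ** 2))
    cond_range = float(x.max() - x.min())
    delta = slope * cond_range
    sign = 0 if slope == 0 else (1 if slope > 0 else -1)

    s2 = rss / df
    if s2 < 1e-12:  # numerically exact fit
        s2 = 0.0
    if moderation is not None:
        s2, df = moderation.moderate(s2, df)
    if s2 <= 0:
        # zero residual variance: the limiting step test
        return (0.0 if abs(delta) > tau else 1.0), sign
    se = math.sqrt(s2 / sxx) * cond_range
    t_right = (abs(delta) - tau) / se
    t_left = (abs(delta) + tau) / se
    p = float(stats.t.sf(t_right, df) + stats.t.sf(t_left, df))
    return min(p, 1.0), sign


@dataclass
class VarianceModeration:
    """Shrink per-feature residual variances toward the pooled variance.

    ``s2_mod = (d0 * s0 + d * s2) / (d0 + d)`` with prior dof ``d0``
    (default 4) and prior variance ``s0`` equal to the mean residual
    variance of the cohort; the t test then uses ``d + d0`` degrees of
    freedom.  A light-weight stand-in for empirical-Bayes moderation
    that narrows the gap to moderated pipelines on short series.
    """

    prior_df: float = 4.0
    prior_s2: float = 0.0

    @classmethod
    def fit(cls, residual_variances: Sequence[float], prior_df: float = 4.0):
        arr = np.asarray(list(residual_variances), dtype=float)
        arr = arr[~np.isnan(arr)]
        return cls(prior_df=prior_df, prior_s2=float(arr.mean()) if len(arr) else 0.0)

    def moderate(self, s2: float, df: float) -> tuple[float, float]:
        if self.prior_df <= 0:
            return s2, df
        return (
            (self.prior_df * self.prior_s2 + df * s2) / (self.prior_df + df),
            df + self.prior_df,
        )


def merge_gene_protein(
    gene_calls: Iterable[DifferentialCall],
    protein_calls: Iterable[DifferentialCall],
    all_features: Iterable[str] | None = None,
) -> list[DifferentialCall]:
    """Combine the two p-value sets into one call per feature.

    Protein evidence wins where present; otherwise the gene call is
    used; features listed in *all_features* with neither become
    non-differential (source ``none``, sign 0, p = 1).  Output covers
    the union of feature ids, sorted for reproducibility.
    """
    genes = {c.feature_id: c for c in gene_calls}
    prots = {c.feature_id: c for c in protein_calls}
    universe = set(genes) | set(prots)
    if all_features is not None:
        universe |= set(all_features)
    merged: list[DifferentialCall] = []
    for fid in sorted(universe):
        if fid in prots:
            merged.append(replace(prots[fid], source="protein"))
        elif fid in genes:
            merged.append(replace(genes[fid], source="gene"))
        else:
            merged.append(DifferentialCall(fid, p_value=1.0, sign=0, source="none"))
    return merged


def estimate_fdr(
    p_values: Sequence[float], method: str = "bh"
) -> np.ndarray:
    """Tail-area FDR (q-values) for a set of independent p-values.

    ``bh`` (default) is Benjamini-Hochberg step-up.  ``density`` is a
    two-component-mixture estimator in the spirit of density-based FDR
    tools: the p-value CDF is estimated by the least concave majorant of
    the ECDF (Grenander), the null weight pi0 by Storey's estimator at
    lambda = 0.5, and Fdr(p) = pi0 * p / F(p), made monotone in p.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    if method == "density":
        return _density_fdr(p)
    raise ValueError(f"unknown FDR method {method!r}")


def _lcm_ecdf(sorted_p: np.ndarray) -> np.ndarray:
    """Least concave majorant of the p-value ECDF, evaluated at sorted_p."""
    n = len(sorted_p)
    px = np.concatenate([[0.0], sorted_p, [1.0]])
    py = np.concatenate([[0.0], np.arange(1, n + 1) / n, [1.0]])
    hull: list[int] = []
    for i in range(len(px)):
        while len(hull) >= 2:
            x1, y1 = px[hull[-2]], py[hull[-2]]
            x2, y2 = px[hull[-1]], py[hull[-1]]
            if (x2 - x1) * (py[i] - y1) - (y2 - y1) * (px[i] - x1) >= 0:
                hull.pop()
            else:
                break
        hull.append(i)
    return np.interp(sorted_p, px[hull], py[hull])


def _density_fdr(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p, kind="stable")
    ps = p[order]
    n = len(p)
    pi0 = min(1.0, float(np.sum(p > 0.5)) / (0.5 * n)) if n else 1.0
    big_f = np.maximum(_lcm_ecdf(ps), 1.0 / n)
    q = np.minimum(pi0 * ps / big_f, 1.0)
    q = np.maximum.accumulate(q)  # tail-area FDR is monotone in p
    out = np.empty(n)
    out[order] = q
    return out


def call_differential(
    calls: Iterable[DifferentialCall], fdr_cut: float = DEFAULT_FDR_CUT
) -> GeneStateMap:
    """Call up/down for q strictly below the FDR cut, else invariant."""
    states: GeneStateMap = {}
    for c in calls:
        if c.q_value is None:
            raise ValueError(f"{c.feature_id}: q_value not populated")
        if c.q_value < fdr_cut and c.sign > 0:
            states[c.feature_id] = "up"
        elif c.q_value < fdr_cut and c.sign < 0:
            states[c.feature_id] = "down"
        else:
            states[c.feature_id] = "invariant"
    return states


def classify_by_fold_change(
    log2fc: Mapping[str, float], cutoff: float = DEFAULT_LOG2FC_CUTOFF
) -> GeneStateMap:
    """The simple fold-change route: |log2 FC| beyond the cutoff."""
    states: GeneStateMap = {}
    for gene, value in log2fc.items():
        if value is None or (isinstance(value, float) and math.isnan(value)):
            states[gene] = "invariant"
        elif value > cutoff:
            states[gene] = "up"
        elif value < -cutoff:
            states[gene] = "down"
        else:
            states[gene] = "invariant"
    return states


def map_to_reactions(
    net: MetabolicNetwork, states: GeneStateMap
) -> ReactionClassification:
    """Project gene states onto reactions through the GPR rules.

    Ternary evaluation with AND = min, OR = max over the coding
    up = +1, invariant = 0, down = -1 (missing genes count 0).  A root
    value of +1 puts the reaction in H, -1 in L, otherwise M; both
    members of a split reversible pair share the same rule and hence the
    same state.
    """
    coded = {g: _STATE_CODE[s] for g, s in states.items()}
    classification: ReactionClassification = {}
    for r in net.reactions:
        classification[r.id] = _CODE_STATE[evaluate_ternary(r.gpr, coded)]
    return classification


def classify_series_route(
    series: Iterable[ExpressionSeries],
    net: MetabolicNetwork,
    fold_threshold: float = DEFAULT_FOLD_THRESHOLD,
    fdr_cut: float = DEFAULT_FDR_CUT,
    min_measurements: int = 4,
    fdr_method: str = "bh",
    moderation_prior_df: float = 0.0,
    metabolic_genes: set[str] | None = None,
) -> tuple[ReactionClassification, GeneStateMap, list[DifferentialCall]]:
    """Full series-route pipeline from raw series to the H/M/L partition.

    Mirrors the flowchart of the growth-rate analysis: restrict to
    metabolic genes, drop short series to the invariant pool, test each
    remaining series against the fold threshold, take protein calls over
    gene calls, FDR-correct the merged set, call up/down below the cut,
    and project onto reactions via the GPRs.
    """
    if metabolic_genes is None:
        metabolic_genes = set()
        for r in net.reactions:
            if r.gpr is not None:
                metabolic_genes |= r.gpr.genes()
    kept, invariant_pool = preprocess(series, metabolic_genes, min_measurements)

    moderation = None
    if moderation_prior_df > 0:
        variances = []
        for s in kept:
            mask = ~np.isnan(s.values)
            x, y = s.conditions[mask], s.values[mask]
            if len(np.unique(x)) < 2:
                continue
            slope, intercept = np.polyfit(x, y, 1)
            variances.append(
                float(np.sum((y - intercept - slope * x) ** 2)) / (len(y) - 2)
            )
        moderation = VarianceModeration.fit(variances, prior_df=moderation_prior_df)

    gene_calls, protein_calls = [], []
    for s in kept:
        p, sign = threshold_regression_test(s, fold_threshold, moderation)
        call = DifferentialCall(s.feature_id, p_value=p, sign=sign, source=s.kind)
        (protein_calls if s.kind == "protein" else gene_calls).append(call)
    merged = merge_gene_protein(gene_calls, protein_calls)
    for fid in sorted(invariant_pool - {c.feature_id for c in merged}):
        merged.append(DifferentialCall(fid, p_value=1.0, sign=0, source="none"))

    qs = estimate_fdr([c.p_value for c in merged], method=fdr_method)
    for c, q in zip(merged, qs):
        c.q_value = float(q)
    states = call_differential(merged, fdr_cut=fdr_cut)
    # genes never measured at all are invariant by assumption
    for g in metabolic_genes - set(states):
        states[g] = "invariant"
    return map_to_reactions(net, states), states, merged
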
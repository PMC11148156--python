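"""Sequence-function correlation engine.

The central statistical object of the package: across the members of an
enzyme family, correlate a numeric residue property (volume, hydropathy,
polarity) at each active-site position with the log10 enzyme activity on
each substrate.  A position whose property rises with activity gives a
positive correlation; a conserved position has no correlation at all
(which is not the same as r = 0).  Strongly correlated positions are
"hot spots" — the natural targets for site-saturation mutagenesis.

Organisation follows the statsmodels convention:
:class:`SequenceFunctionModel` is built from the data, and ``fit()``
returns a :class:`SequenceFunctionResults` carrying the full correlation
grid, combined-property regressions, hot-spot rankings, exports, and a
``summary()`` table.

The correlation is the Pearson product-moment coefficient on
(property, log10 activity) pairs, matching the linearity of the
combined-volume regressions; a Spearman option is available for
robustness.  Below-detection activities are excluded by default
(flooring them at the detection limit fabricates leverage points on the
log scale, but is available as a policy).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .position_map import SiteStateTable
from .profiles import PropertyScale, aggregate_property
from .seqio import GAP, ActivityTable

#: minimum number of (property, activity) pairs for a defined correlation;
#: two points always give |r| = 1, so 3 is the floor.
MIN_N = 3

STATUS_OK = "ok"
STATUS_CONSERVED = "conserved"
STATUS_INSUFFICIENT = "insufficient"


# ---------------------------------------------------------------------------
# log activities


def log_activities(table: ActivityTable, nd_policy: str = "exclude") -> pd.DataFrame:
    """Tidy log10 activities: one row per (enzyme, substrate).

    Columns: enzyme, substrate, value (log10 of the rate in 1/s), floored
    (True where a below-detection cell was set to log10 of the detection
    floor).  With ``nd_policy="exclude"`` below-detection cells are
    omitted; with ``"floor"`` they are kept at the floor and flagged.  A
    measured rate of exactly 0 is treated as below detection.
    """
    if nd_policy not in ("exclude", "floor"):
        raise ValueError(f"nd_policy must be 'exclude' or 'floor', got {nd_policy!r}")
    rows = []
    floor_value = np.log10(table.detection_floor)
    for enzyme in table.enzymes:
        for substrate in table.substrates:
            rate = table.rates.loc[enzyme, substrate]
            below = pd.isna(rate) or rate == 0
            if below and nd_policy == "exclude":
                continue
            value = floor_value if below else np.log10(rate)
            rows.append({"enzyme": enzyme, "substrate": substrate,
                         "value": float(value), "floored": bool(below)})
    return pd.DataFrame(rows, columns=["enzyme", "substrate", "value", "floored"])


# ---------------------------------------------------------------------------
# per-position correlations


@dataclass(frozen=True)
class CorrelationResult:
    """Correlation of one position's property with log activity on one substrate."""

    position: int
    substrate: str
    r: float | None
    n_used: int
    status: str  # ok | conserved | insufficient

    def __post_init__(self) -> None:
        if (self.status == STATUS_OK) != (self.r is not None):
            raise ValueError("r must be present exactly when status is 'ok'")
        if self.r is not None and abs(self.r) > 1 + 1e-12:
            raise ValueError(f"|r| > 1: {self.r}")
        if self.status == STATUS_OK and self.n_used < MIN_N:
            raise ValueError("ok correlation with fewer than 3 pairs")


def _pairs_for(states: SiteStateTable, scale: PropertyScale, position: int,
               logact: pd.DataFrame, substrate: str) -> tuple[np.ndarray, np.ndarray, int]:
    sub = logact[logact["substrate"] == substrate]
    props, acts = [], []
    for _, row in sub.iterrows():
        enzyme = row["enzyme"]
        if enzyme not in states.sequences:
            continue
        state = states.state(enzyme, position)
        if state == GAP or state not in scale:
            continue
        props.append(scale[state])
        acts.append(row["value"])
    return np.asarray(props, dtype=float), np.asarray(acts, dtype=float), len(props)


def position_activity_correlation(states: SiteStateTable, scale: PropertyScale,
                                  logact: pd.DataFrame, substrate: str,
                                  *, method: str = "pearson",
                                  min_n: int = MIN_N) -> list[CorrelationResult]:
    """One :class:`CorrelationResult` per scheme position for one substrate.

    Enzymes enter the computation only if they have both an ungapped,
    known residue at the position and a usable log activity.  A position
    whose property is constant across the used enzymes is ``conserved``;
    fewer than ``min_n`` usable pairs — or activities with zero variance,
    which leave Pearson's r undefined — give ``insufficient``.
    """
    if substrate not in set(logact["substrate"]):
        raise KeyError(f"substrate {substrate!r} has no activities")
    if method not in ("pearson", "spearman"):
        raise ValueError(f"method must be 'pearson' or 'spearman', got {method!r}")
    results = []
    for position in states.positions:
        props, acts, n = _pairs_for(states, scale, position, logact, substrate)
        if n > 0 and np.ptp(props) == 0:
            results.append(CorrelationResult(position, substrate, None, n, STATUS_CONSERVED))
            continue
        if n < min_n or np.ptp(acts) == 0:
            results.append(CorrelationResult(position, substrate, None, n, STATUS_INSUFFICIENT))
            continue
        if method == "pearson":
            r = float(stats.pearsonr(props, acts).statistic)
        else:
            r = float(stats.spearmanr(props, acts).statistic)
        results.append(CorrelationResult(position, substrate, r, n, STATUS_OK))
    return results


# ---------------------------------------------------------------------------
# heatmap grid


def heatmap_matrix(results: Iterable[CorrelationResult],
                   positions: Sequence[int] | None = None,
                   substrates: Sequence[str] | None = None,
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Positions x substrates grids of r values and statuses.

    Cells without an ``ok`` correlation carry NaN in the value grid (the
    neutral color in a heatmap) while the status grid records why —
    conserved and insufficient cells are never exported as numeric 0.
    """
    results = list(results)
    if positions is None:
        positions = list(dict.fromkeys(res.position for res in results))
    if substrates is None:
        substrates = list(dict.fromkeys(res.substrate for res in results))
    values = pd.DataFrame(np.nan, index=pd.Index(positions, name="position"),
                          columns=pd.Index(substrates, name="substrate"))
    status = pd.DataFrame("missing", index=values.index, columns=values.columns)
    for res in results:
        if res.position in positions and res.substrate in substrates:
            status.loc[res.position, res.substrate] = res.status
            if res.status == STATUS_OK:
                values.loc[res.position, res.substrate] = res.r
    return values, status


def heatmap_to_tsv(values: pd.DataFrame, status: pd.DataFrame, path) -> None:
    """Tidy TSV export of a heatmap grid: position, substrate, r, status."""
    rows = [
        {"position": p, "substrate": s,
         "r": values.loc[p, s], "status": status.loc[p, s]}
        for p in values.index for s in values.columns
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def heatmap_from_tsv(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    tidy = pd.read_csv(path, sep="\t")
    values = tidy.pivot(index="position", columns="substrate", values="r")
    status = tidy.pivot(index="position", columns="substrate", values="status")
    # preserve file order of positions/substrates
    pos_order = list(dict.fromkeys(tidy["position"]))
    sub_order = list(dict.fromkeys(tidy["substrate"]))
    return values.loc[pos_order, sub_order], status.loc[pos_order, sub_order]


# ---------------------------------------------------------------------------
# combined-property regression


@dataclass(frozen=True)
class RegressionResult:
    """OLS of log10 activity on a summed residue property."""

    positions: tuple[int, ...]
    substrate: str
    slope: float | None
    intercept: float | None
    r: float | None
    n_used: int
    stderr: float | None
    status: str  # ok | conserved | insufficient

    def predict(self, combined_property: np.ndarray) -> np.ndarray:
        if self.status != STATUS_OK:
            raise ValueError(f"no fitted line (status {self.status!r})")
        return self.intercept + self.slope * np.asarray(combined_property, dtype=float)


def combined_property_regression(states: SiteStateTable, scale: PropertyScale,
                                 positions: Sequence[int], logact: pd.DataFrame,
                                 substrate: str, *, min_n: int = MIN_N) -> RegressionResult:
    """Regress log10 activity on the summed property over ``positions``.

    Returns the OLS slope and intercept plus the Pearson r of the same
    pairs.  A constant combined property across the usable enzymes makes
    the slope undefined (status ``conserved``).
    """
    sub = logact[logact["substrate"] == substrate]
    if sub.empty:
        raise KeyError(f"substrate {substrate!r} has no activities")
    combined = aggregate_property(states, scale, positions, "sum")
    xs, ys = [], []
    for _, row in sub.iterrows():
        enzyme = row["enzyme"]
        if enzyme in combined.index and np.isfinite(combined[enzyme]):
            xs.append(combined[enzyme])
            ys.append(row["value"])
    x, y = np.asarray(xs), np.asarray(ys)
    n = len(x)
    key = (tuple(positions), substrate)
    if n > 0 and np.ptp(x) == 0:
        return RegressionResult(*key, None, None, None, n, None, STATUS_CONSERVED)
    if n < min_n or np.ptp(y) == 0:
        return RegressionResult(*key, None, None, None, n, None, STATUS_INSUFFICIENT)
    fit = stats.linregress(x, y)
    return RegressionResult(*key, float(fit.slope), float(fit.intercept),
                            float(fit.rvalue), n, float(fit.stderr), STATUS_OK)


# ---------------------------------------------------------------------------
# hot spots


def hotspot_ranking(results: Iterable[CorrelationResult], *,
                    min_abs_r: float = 0.7, min_n: int = MIN_N) -> pd.DataFrame:
    """Rank positions by correlation strength across substrates.

    A position is ranked by the maximum |r| over its ``ok`` correlations
    with at least ``min_n`` enzymes, keeping only positions whose best
    |r| meets ``min_abs_r``; ties break by mean |r|, then by position
    number.  Conserved positions are never ranked.  Each ranked position
    lists the substrates supporting it (those meeting both thresholds).
    """
    if not 0 < min_abs_r <= 1:
        raise ValueError(f"min_abs_r must be in (0, 1], got {min_abs_r}")
    if min_n < MIN_N:
        raise ValueError(f"min_n must be >= {MIN_N}, got {min_n}")
    usable: dict[int, list[CorrelationResult]] = {}
    for res in results:
        if res.status == STATUS_OK and res.n_used >= min_n:
            usable.setdefault(res.position, []).append(res)
    rows = []
    for position, group in usable.items():
        abs_rs = np.array([abs(res.r) for res in group])
        if abs_rs.max() < min_abs_r:
            continue
        supporting = sorted(res.substrate for res in group if abs(res.r) >= min_abs_r)
        rows.append({
            "position": position,
            "max_abs_r": float(abs_rs.max()),
            "mean_abs_r": float(abs_rs.mean()),
            "n_substrates": len(group),
            "supporting_substrates": ",".join(supporting),
        })
    frame = pd.DataFrame(rows, columns=["position", "max_abs_r", "mean_abs_r",
                                        "n_substrates", "supporting_substrates"])
    if frame.empty:
        return frame
    frame = frame.sort_values(
        by=["max_abs_r", "mean_abs_r", "position"],
        ascending=[False, False, True], kind="mergesort",
    ).reset_index(drop=True)
    frame.index = pd.RangeIndex(1, len(frame) + 1, name="rank")
    return frame


# ---------------------------------------------------------------------------
# model / results objects


class SequenceFunctionModel:
    """Sequence-function correlation model for an enzyme family.

    Parameters
    ----------
    states
        Active-site residue states per family member (from
        :func:`sitefunc.position_map.extract_site_states`).
    activities
        Enzyme x substrate rate table in 1/s.
    scale
        Residue property to correlate (default: residue volume).
    nd_policy
        How below-detection rates enter the log scale: ``"exclude"``
        (default) or ``"floor"``.
    method
        ``"pearson"`` (default) or ``"spearman"``.
    """

    def __init__(self, states: SiteStateTable, activities: ActivityTable,
                 scale: PropertyScale | None = None, *,
                 nd_policy: str = "exclude", method: str = "pearson",
                 substrates: Sequence[str] | None = None, min_n: int = MIN_N):
        from .profiles import VOLUME  # default scale

        self.states = states
        self.activities = activities
        self.scale = VOLUME if scale is None else scale
        self.nd_policy = nd_policy
        self.method = method
        self.min_n = min_n
        self.substrates = list(activities.substrates) if substrates is None else list(substrates)
        unknown = set(self.substrates) - set(activities.substrates)
        if unknown:
            raise KeyError(f"substrates not in activity table: {sorted(unknown)}")
        overlap = set(states.sequences) & set(activities.enzymes)
        if len(overlap) < min_n:
            raise ValueError(
                f"only {len(overlap)} enzymes shared between states and activities; "
                f"need at least {min_n}"
            )

    @classmethod
    def from_alignment(cls, alignment, scheme, activities, scale=None, **kwargs):
        """Build directly from an alignment and a site scheme."""
        from .position_map import build_position_map, extract_site_states

        pmap = build_position_map(alignment, scheme.template_id)
        states = extract_site_states(alignment, pmap, scheme)
        return cls(states, activities, scale, **kwargs)

    def fit(self) -> "SequenceFunctionResults":
        logact = log_activities(self.activities, self.nd_policy)
        results = []
        for substrate in self.substrates:
            if substrate not in set(logact["substrate"]):
                # every activity below detection and excluded
                results.extend(
                    CorrelationResult(p, substrate, None, 0, STATUS_INSUFFICIENT)
                    for p in self.states.positions
                )
                continue
            results.extend(position_activity_correlation(
                self.states, self.scale, logact, substrate,
                method=self.method, min_n=self.min_n,
            ))
        return SequenceFunctionResults(self, logact, results)


class SequenceFunctionResults:
    """Fitted correlation grid with rankings, regressions, and exports."""

    def __init__(self, model: SequenceFunctionModel, logact: pd.DataFrame,
                 correlations: list[CorrelationResult]):
        self.model = model
        self.log_activities = logact
        self.correlations = correlations
        self.values, self.status = heatmap_matrix(
            correlations, positions=model.states.positions, substrates=model.substrates,
        )

    def hotspots(self, min_abs_r: float = 0.7, min_n: int = MIN_N) -> pd.DataFrame:
        return hotspot_ranking(self.correlations, min_abs_r=min_abs_r, min_n=min_n)

    def combined_regression(self, positions: Sequence[int],
                            substrate: str) -> RegressionResult:
        return combined_property_regression(
            self.model.states, self.model.scale, positions,
            self.log_activities, substrate, min_n=self.model.min_n,
        )

    def to_tsv(self, path) -> None:
        heatmap_to_tsv(self.values, self.status, path)

    def plot_heatmap(self, ax=None):
        from .plotting import plot_correlation_heatmap

        return plot_correlation_heatmap(self.values, self.status,
                                        scheme=self.model.states.scheme, ax=ax)

    def summary(self) -> str:
        """Human-readable run report."""
        model = self.model
        n_ok = sum(res.status == STATUS_OK for res in self.correlations)
        n_cons = sum(res.status == STATUS_CONSERVED for res in self.correlations)
        n_ins = sum(res.status == STATUS_INSUFFICIENT for res in self.correlations)
        lines = [
            "Sequence-function correlation results",
            "=" * 37,
            f"property scale:     {model.scale.name} ({model.scale.units})",
            f"correlation:        {model.method}",
            f"below-detection:    {model.nd_policy}",
            f"positions:          {len(model.states.positions)}",
            f"substrates:         {len(model.substrates)}",
            f"enzymes:            {len(model.states.sequences)}",
            f"cells ok/conserved/insufficient: {n_ok}/{n_cons}/{n_ins}",
            "",
            "correlation grid (r; '.' = conserved, 'x' = insufficient):",
        ]
        grid = self.values.copy().round(2).astype(object)
        grid[self.status == STATUS_CONSERVED] = "."
        grid[self.status == STATUS_INSUFFICIENT] = "x"
        lines.append(grid.to_string())
        top = self.hotspots()
        if not top.empty:
            lines += ["", "hot spots (max |r| >= 0.7):", top.to_string()]
        return "\n".join(lines)
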
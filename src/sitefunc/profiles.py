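"""Amino-acid property scales, clade diversity profiles, and candidate selection.

Three published scales ship as built-ins — residue volume (Zamyatnin,
1972, in cubic angstroms), hydropathy (Kyte & Doolittle, 1982), and
polarity (Grantham, 1974) — and users may register their own from YAML.
On top of the scales: per-(position, clade) residue-frequency profiles,
cluster-level property aggregation per sequence ("combined volume"), and
criterion-based ranking of family members for experimental follow-up.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .position_map import SiteStateTable
from .seqio import AMINO_ACIDS, GAP

AGGREGATORS = {"sum": np.sum, "mean": np.mean, "max": np.max}
COMPARATORS = {"<=": np.less_equal, ">=": np.greater_equal}


@dataclass(frozen=True)
class PropertyScale:
    """A numeric value for each of the 20 canonical amino acids."""

    name: str
    units: str
    values: Mapping[str, float]
    citation: str = ""

    def __post_init__(self) -> None:
        missing = set(AMINO_ACIDS) - set(self.values)
        extra = set(self.values) - set(AMINO_ACIDS)
        if missing or extra:
            raise ValueError(
                f"scale {self.name!r} must cover exactly the 20 canonical residues; "
                f"missing {sorted(missing)}, extra {sorted(extra)}"
            )
        if not all(np.isfinite(v) for v in self.values.values()):
            raise ValueError(f"scale {self.name!r} contains non-finite values")

    def __getitem__(self, residue: str) -> float:
        return float(self.values[residue])

    def __contains__(self, residue: str) -> bool:
        return residue in self.values

    @classmethod
    def from_yaml(cls, path) -> "PropertyScale":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(name=doc["name"], units=doc.get("units", ""),
                   values={str(k): float(v) for k, v in doc["values"].items()},
                   citation=doc.get("citation", ""))


#: Residue volumes in A^3 (Zamyatnin, Prog. Biophys. Mol. Biol. 24, 1972).
VOLUME = PropertyScale(
    name="volume",
    units="A^3",
    citation="Zamyatnin (1972) Prog Biophys Mol Biol 24:107-123",
    values={
        "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5,
        "Q": 143.8, "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7,
        "L": 166.7, "K": 168.6, "M": 162.9, "F": 189.9, "P": 112.7,
        "S": 89.0, "T": 116.1, "W": 227.8, "Y": 193.6, "V": 140.0,
    },
)

#: Hydropathy index (Kyte & Doolittle, J. Mol. Biol. 157, 1982).
HYDROPATHY = PropertyScale(
    name="hydropathy",
    units="dimensionless",
    citation="Kyte & Doolittle (1982) J Mol Biol 157:105-132",
    values={
        "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
        "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
        "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
        "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
    },
)

#: Polarity (Grantham, Science 185, 1974).
POLARITY = PropertyScale(
    name="polarity",
    units="dimensionless",
    citation="Grantham (1974) Science 185:862-864",
    values={
        "A": 8.1, "R": 10.5, "N": 11.6, "D": 13.0, "C": 5.5,
        "Q": 10.5, "E": 12.3, "G": 9.0, "H": 10.4, "I": 5.2,
        "L": 4.9, "K": 11.3, "M": 5.7, "F": 5.2, "P": 8.0,
        "S": 9.2, "T": 8.6, "W": 5.4, "Y": 6.2, "V": 5.9,
    },
)


def builtin_scales() -> dict[str, PropertyScale]:
    """The shipped scales, keyed by name."""
    return {s.name: s for s in (VOLUME, HYDROPATHY, POLARITY)}


# ---------------------------------------------------------------------------
# diversity profiles


@dataclass(frozen=True)
class DiversityProfile:
    """Residue frequencies at one position within one clade.

    Gap states are excluded from the count ``n``; frequencies sum to 1.
    """

    position: int
    clade: str
    frequencies: Mapping[str, float]
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("diversity profile needs n >= 1")
        total = sum(self.frequencies.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"frequencies sum to {total}, expected 1")


def diversity_profiles(states: SiteStateTable,
                       clades: Mapping[str, str]) -> list[DiversityProfile]:
    """One residue-frequency profile per (position, clade).

    Every sequence in ``states`` must carry a clade label.  A clade whose
    members are all gapped at a position is omitted with a warning.
    """
    missing = [s for s in states.sequences if s not in clades]
    if missing:
        raise KeyError(f"sequences without a clade label: {missing}")
    profiles: list[DiversityProfile] = []
    clade_names = sorted(set(clades[s] for s in states.sequences))
    for position in states.positions:
        for clade in clade_names:
            members = [s for s in states.sequences if clades[s] == clade]
            residues = [states.state(s, position) for s in members]
            residues = [r for r in residues if r != GAP]
            if not residues:
                warnings.warn(
                    f"clade {clade!r} has no ungapped state at position {position}; "
                    "profile omitted"
                )
                continue
            counts = pd.Series(residues).value_counts()
            n = int(counts.sum())
            profiles.append(DiversityProfile(
                position=position, clade=clade,
                frequencies={res: c / n for res, c in counts.items()}, n=n,
            ))
    return profiles


def profiles_to_frame(profiles: Iterable[DiversityProfile]) -> pd.DataFrame:
    """Tidy export: one row per (position, clade, residue)."""
    rows = [
        {"position": p.position, "clade": p.clade, "residue": res,
         "frequency": freq, "n": p.n}
        for p in profiles for res, freq in sorted(p.frequencies.items())
    ]
    return pd.DataFrame(rows, columns=["position", "clade", "residue", "frequency", "n"])


# ---------------------------------------------------------------------------
# property aggregation


def aggregate_property(states: SiteStateTable, scale: PropertyScale,
                       positions: Iterable[int] | None = None,
                       aggregator: str = "sum") -> pd.Series:
    """Per-sequence aggregate of a property over a set of positions.

    Sequences with a gap or an unknown residue (X) at any requested
    position get ``NaN`` — they are ineligible, never silently scored 0.
    The default aggregator is ``sum`` (the "combined volume" of a
    cluster); ``mean`` and ``max`` are also available.
    """
    if aggregator not in AGGREGATORS:
        raise ValueError(f"unknown aggregator {aggregator!r}; expected one of {sorted(AGGREGATORS)}")
    positions = list(states.positions) if positions is None else list(positions)
    unknown = set(positions) - set(states.positions)
    if unknown:
        raise KeyError(f"positions not in state table: {sorted(unknown)}")
    agg = AGGREGATORS[aggregator]
    out = {}
    for seq in states.sequences:
        residues = [states.state(seq, p) for p in positions]
        if any(r == GAP or r not in scale for r in residues):
            out[seq] = np.nan
        else:
            out[seq] = float(agg([scale[r] for r in residues]))
    return pd.Series(out, name=f"{scale.name}_{aggregator}")


# ---------------------------------------------------------------------------
# candidate selection


@dataclass(frozen=True)
class SelectionCriterion:
    """A pass/fail predicate on a cluster-level property aggregate."""

    cluster: str
    scale: str
    comparator: str  # "<=" or ">="
    threshold: float
    aggregator: str = "sum"

    def __post_init__(self) -> None:
        if self.comparator not in COMPARATORS:
            raise ValueError(f"comparator must be one of {sorted(COMPARATORS)}")
        if self.aggregator not in AGGREGATORS:
            raise ValueError(f"aggregator must be one of {sorted(AGGREGATORS)}")

    @property
    def label(self) -> str:
        return f"{self.cluster}:{self.scale}_{self.aggregator}"

    @classmethod
    def from_dict(cls, doc: Mapping) -> "SelectionCriterion":
        return cls(cluster=doc["cluster"], scale=doc["scale"],
                   comparator=doc["comparator"], threshold=float(doc["threshold"]),
                   aggregator=doc.get("aggregator", "sum"))


def select_candidates(states: SiteStateTable,
                      criteria: Iterable[SelectionCriterion],
                      scales: Mapping[str, PropertyScale] | None = None) -> pd.DataFrame:
    """Annotate and rank family members against property criteria.

    Returns one row per sequence with, for each criterion, the aggregate
    value and its pass flag, plus ``passes_all``.  Rows are ordered by
    the first criterion's aggregate — ascending for a ``<=`` criterion,
    descending for ``>=`` — with ties broken by sequence id.  A sequence
    with a gap/unknown state in a criterion's cluster fails that
    criterion (value NaN).
    """
    criteria = list(criteria)
    if not criteria:
        raise ValueError("need at least one selection criterion")
    scales = builtin_scales() if scales is None else dict(scales)
    scheme = states.scheme
    result = pd.DataFrame(index=pd.Index(states.sequences, name="sequence"))
    for crit in criteria:
        if crit.cluster not in scheme.clusters:
            raise KeyError(f"criterion references unknown cluster {crit.cluster!r}")
        if crit.scale not in scales:
            raise KeyError(f"criterion references unknown scale {crit.scale!r}")
        positions = [s.position for s in scheme.clusters[crit.cluster]]
        values = aggregate_property(states, scales[crit.scale], positions, crit.aggregator)
        passed = COMPARATORS[crit.comparator](values, crit.threshold)
        passed &= values.notna()
        result[crit.label] = values
        result[f"{crit.label}_pass"] = passed.astype(bool)
    pass_cols = [c for c in result.columns if c.endswith("_pass")]
    result["passes_all"] = result[pass_cols].all(axis=1)
    first = criteria[0]
    ascending = first.comparator == "<="
    result = result.sort_values(
        by=[first.label, "sequence"], ascending=[ascending, True],
        kind="mergesort", na_position="last",
    )
    result["rank"] = np.arange(1, len(result) + 1)
    return result
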
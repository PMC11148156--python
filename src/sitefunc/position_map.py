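"""Template-anchored active-site mapping.

The coordinate system for an enzyme family is the residue numbering of a
template structure (for the 4-phenol oxidoreductases: the eugenol oxidase
from Rhodococcus jostii RHA1, RjEUGO, PDB 5FXP).  A :class:`PositionMap`
ties the template's 1-based ungapped positions to 0-based alignment
columns; :func:`extract_site_states` then reads, for every sequence, the
residue occupying each active-site position, and
:func:`renumber_position` converts template numbering into any homolog's
own numbering through the shared columns.

Template positions are 1-based throughout (the crystal-structure
convention); alignment columns are 0-based internally and 1-based only in
user-facing reports.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .seqio import AMINO_ACIDS, GAP, Alignment

_TOKEN_RE = re.compile(r"^([A-Z])(\d+)$")


class SiteSchemeError(ValueError):
    """Raised when a site scheme is inconsistent or contradicts the template."""


@dataclass(frozen=True)
class SitePosition:
    """One active-site position: expected template residue + 1-based position."""

    residue: str
    position: int

    def __post_init__(self) -> None:
        if self.residue not in AMINO_ACIDS:
            raise SiteSchemeError(f"unknown residue code {self.residue!r}")
        if self.position < 1:
            raise SiteSchemeError(f"template position must be >= 1, got {self.position}")

    @classmethod
    def from_token(cls, token: str) -> "SitePosition":
        m = _TOKEN_RE.match(token.strip())
        if m is None:
            raise SiteSchemeError(f"cannot parse site token {token!r} (expected e.g. 'Y91')")
        return cls(m.group(1), int(m.group(2)))

    def token(self) -> str:
        return f"{self.residue}{self.position}"


@dataclass
class SiteScheme:
    """Named functional clusters of template active-site positions.

    ``clusters`` maps a cluster name (e.g. P, T, H, W, A) to its
    :class:`SitePosition` list.  Positions must be unique across clusters.
    """

    template_id: str
    clusters: dict[str, list[SitePosition]]

    def __post_init__(self) -> None:
        if not self.template_id:
            raise SiteSchemeError("scheme needs a template id")
        if len(self.clusters) != len(set(self.clusters)):
            raise SiteSchemeError("duplicate cluster name")
        seen: dict[int, str] = {}
        for name, sites in self.clusters.items():
            for site in sites:
                if site.position in seen:
                    raise SiteSchemeError(
                        f"position {site.position} appears in clusters "
                        f"{seen[site.position]!r} and {name!r}"
                    )
                seen[site.position] = name

    @property
    def positions(self) -> list[int]:
        """All template positions, in cluster order then ascending."""
        return [s.position for sites in self.clusters.values() for s in sorted(sites, key=lambda x: x.position)]

    def expected_residue(self, position: int) -> str:
        for sites in self.clusters.values():
            for s in sites:
                if s.position == position:
                    return s.residue
        raise KeyError(f"position {position} not in scheme")

    def cluster_of(self, position: int) -> str:
        for name, sites in self.clusters.items():
            if any(s.position == position for s in sites):
                return name
        raise KeyError(f"position {position} not in scheme")

    @classmethod
    def from_yaml(cls, path) -> "SiteScheme":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "SiteScheme":
        try:
            template_id = doc["template"]
            clusters_doc = doc["clusters"]
        except (KeyError, TypeError) as exc:
            raise SiteSchemeError(f"scheme file missing key: {exc}") from exc
        clusters = {
            str(name): [SitePosition.from_token(tok) for tok in tokens]
            for name, tokens in clusters_doc.items()
        }
        return cls(template_id=template_id, clusters=clusters)

    def to_dict(self) -> dict:
        return {
            "template": self.template_id,
            "clusters": {name: [s.token() for s in sites] for name, sites in self.clusters.items()},
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def eugo_first_shell(template_id: str = "RjEUGO") -> SiteScheme:
    """The 17 first-shell positions of the 4-phenol oxidoreductase pocket.

    RjEUGO (PDB 5FXP) numbering, grouped into the five functional
    clusters: P binds the substrate phenolate; T lines the entrance
    tunnel near one o-substituent; H contacts the other o-substituent;
    W is the polar cluster at the p-substituent; A is the hydrophobic
    cluster restricting the p-substituent.
    """
    tok = SitePosition.from_token
    return SiteScheme(
        template_id=template_id,
        clusters={
            "P": [tok(t) for t in ("Y91", "Y471", "R472")],
            "T": [tok(t) for t in ("G165", "V166", "I427")],
            "H": [tok(t) for t in ("H390", "G392")],
            "W": [tok(t) for t in ("D151", "Y169", "R278", "E378", "Q425")],
            "A": [tok(t) for t in ("M282", "L381", "L438", "V436")],
        },
    )


@dataclass
class PositionMap:
    """Bijection between a template's ungapped positions and alignment columns.

    ``columns[i]`` is the 0-based alignment column of 1-based template
    position ``i + 1``; both coordinates are strictly increasing.
    """

    template_id: str
    columns: np.ndarray
    n_alignment_columns: int
    _col_to_pos: dict[int, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.columns = np.asarray(self.columns, dtype=int)
        if np.any(np.diff(self.columns) <= 0):
            raise ValueError("alignment columns must be strictly increasing")
        self._col_to_pos = {int(c): i + 1 for i, c in enumerate(self.columns)}

    @property
    def template_length(self) -> int:
        return len(self.columns)

    def column_of(self, template_pos: int) -> int:
        """0-based alignment column of a 1-based template position."""
        if not 1 <= template_pos <= self.template_length:
            raise IndexError(
                f"template position {template_pos} outside 1..{self.template_length}"
            )
        return int(self.columns[template_pos - 1])

    def position_at(self, column: int) -> int | None:
        """1-based template position at a 0-based column, or None if the template is gapped there."""
        return self._col_to_pos.get(int(column))


def build_position_map(alignment: Alignment, template_id: str) -> PositionMap:
    """Map each ungapped template position to its alignment column."""
    if template_id not in alignment:
        raise KeyError(f"template id {template_id!r} not in alignment")
    row = alignment[template_id].residues
    cols = np.flatnonzero(np.frombuffer(row.encode(), dtype="S1") != GAP.encode())
    return PositionMap(template_id=template_id, columns=cols,
                       n_alignment_columns=alignment.n_columns)


@dataclass
class SiteStateTable:
    """Residue states at active-site positions for every family member.

    ``states`` is a sequences x positions DataFrame of single-character
    residues; a gap at a position is stored as ``-`` and is excluded from
    property aggregation and correlation downstream (never imputed).
    """

    states: pd.DataFrame
    scheme: SiteScheme

    @property
    def positions(self) -> list[int]:
        return list(self.states.columns)

    @property
    def sequences(self) -> list[str]:
        return list(self.states.index)

    def state(self, seq_id: str, position: int) -> str:
        return self.states.loc[seq_id, position]

    def to_tsv(self, path) -> None:
        self.states.to_csv(path, sep="\t", index_label="sequence")


def extract_site_states(alignment: Alignment, pmap: PositionMap, scheme: SiteScheme,
                        *, check_template: bool = True) -> SiteStateTable:
    """Read every sequence's residue at each scheme position.

    By default the template's observed residues must equal the residues
    the scheme declares (this catches off-by-one numbering between the
    scheme and the alignment); pass ``check_template=False`` when the
    scheme is anchored on a homologous template.
    """
    if pmap.template_id not in alignment:
        raise KeyError(f"template id {pmap.template_id!r} not in alignment")
    positions = scheme.positions
    for p in positions:
        if p > pmap.template_length:
            raise SiteSchemeError(
                f"scheme position {p} beyond template length {pmap.template_length}"
            )
    cols = [pmap.column_of(p) for p in positions]
    data = {
        rec.id: [rec.residues[c] for c in cols]
        for rec in alignment.records
    }
    states = pd.DataFrame.from_dict(data, orient="index", columns=positions)
    states = states.loc[[rec.id for rec in alignment.records]]
    if check_template:
        for p in positions:
            observed = states.loc[pmap.template_id, p]
            expected = scheme.expected_residue(p)
            if observed != expected:
                raise SiteSchemeError(
                    f"template residue mismatch at position {p}: scheme expects "
                    f"{expected!r}, alignment has {observed!r} "
                    "(check the numbering, or pass check_template=False)"
                )
    return SiteStateTable(states=states, scheme=scheme)


def renumber_position(template_pos: int, map_from: PositionMap,
                      map_to: PositionMap) -> int | None:
    """Convert a template position into another sequence's own numbering.

    Both maps must come from the same alignment.  Returns the 1-based
    ungapped position of the target sequence at the shared column, or
    ``None`` if the target sequence has a gap there.
    """
    if map_from.n_alignment_columns != map_to.n_alignment_columns:
        raise ValueError("position maps were not built from the same alignment")
    column = map_from.column_of(template_pos)
    return map_to.position_at(column)
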
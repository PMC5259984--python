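"""188-dimension composition + physicochemical CTD fingerprint.

The fingerprint concatenates the 20 amino-acid composition percentages with a
21-value CTD (composition / transition / distribution) block for each of eight
physicochemical properties, each property partitioning the 20 residues into
three groups. 20 + 8 x 21 = 188 features, all on a 0-100 percentage scale.

Per property with groups (g1, g2, g3):

* C_i  = 100 x (residues in group i) / L                       (3 values)
* T_ij = 100 x (adjacent pairs crossing groups i,j) / (L - 1)  (3 values)
* D_ij = 100 x (position of the P_j-th group-i residue) / L    (15 values)
  where P_0 = 1 and P_j = floor(N*j/4) for j = 1..4 (clamped to >= 1),
  N being the group-i occurrence count. Positions are 1-based. A group with
  no occurrences contributes five zeros.

Only the hydrophobicity partition (neutral / polar / hydrophobic) is fixed by
the method's definition; the other seven ship in a versioned grouping file
(``data/ctd_groupings.cfg``) following the standard CTD descriptor tables and
can be overridden.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .seqio import AMINO_ALPHABET, ProteinRecord, FeatureTable

GROUP_TAGS = ("g1", "g2", "g3")

# Anchor partition: neutral / polar / hydrophobic.
HYDROPHOBICITY_GROUPS = ("GASTPHY", "RKEDQN", "CVLIMFW")


class DomainError(ValueError):
    """Input outside the domain of a descriptor (e.g. too short)."""


@dataclass(frozen=True)
class PropertyGrouping:
    """A named 3-way partition of an alphabet (default: the 20 residues)."""

    property_name: str
    groups: tuple[frozenset, frozenset, frozenset]
    alphabet: str = AMINO_ALPHABET

    def __post_init__(self) -> None:
        g1, g2, g3 = self.groups
        if g1 & g2 or g1 & g3 or g2 & g3:
            raise ValueError(f"{self.property_name}: groups overlap")
        if g1 | g2 | g3 != set(self.alphabet):
            raise ValueError(
                f"{self.property_name}: groups do not cover the alphabet "
                f"exactly (union={sorted(g1 | g2 | g3)})"
            )

    @classmethod
    def from_strings(cls, name: str, g1: str, g2: str, g3: str,
                     alphabet: str = AMINO_ALPHABET) -> "PropertyGrouping":
        return cls(name, (frozenset(g1), frozenset(g2), frozenset(g3)), alphabet)

    def group_of(self) -> dict[str, int]:
        """Letter -> group index (0, 1, 2)."""
        mapping = {}
        for gi, group in enumerate(self.groups):
            for letter in group:
                mapping[letter] = gi
        return mapping


@dataclass(frozen=True)
class GroupingSet:
    """The ordered list of 8 property partitions behind the 188D layout."""

    groupings: tuple[PropertyGrouping, ...]

    def __post_init__(self) -> None:
        if len(self.groupings) != 8:
            raise ValueError(f"expected 8 property groupings, got {len(self.groupings)}")
        names = [g.property_name for g in self.groupings]
        if len(set(names)) != len(names):
            raise ValueError("property names must be unique")


def load_groupings(path: str | Path | None = None) -> GroupingSet:
    """Load the 8 CTD partitions from a grouping file (default: bundled)."""
    if path is None:
        text = (resources.files("pretata") / "data" / "ctd_groupings.cfg").read_text()
    else:
        text = Path(path).read_text()
    groupings = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if ":" not in line:
            raise ValueError(f"grouping file line {lineno}: missing ':'")
        name, rest = line.split(":", 1)
        parts = [p.strip().upper() for p in rest.split(",")]
        if len(parts) != 3:
            raise ValueError(
                f"grouping file line {lineno}: expected 3 comma-separated groups"
            )
        groupings.append(PropertyGrouping.from_strings(name.strip(), *parts))
    return GroupingSet(tuple(groupings))


DEFAULT_GROUPINGS = load_groupings()


# ---------------------------------------------------------------------------
# Descriptor blocks
# ---------------------------------------------------------------------------

def aa_composition(seq: str) -> np.ndarray:
    """Percentage of each residue, in ACDEFGHIKLMNPQRSTVWY order (sums to 100)."""
    if not seq:
        raise DomainError("empty sequence")
    L = len(seq)
    counts = np.array([seq.count(a) for a in AMINO_ALPHABET], dtype=float)
    return counts / L * 100.0


def ctd_for_property(seq: str, grouping: PropertyGrouping) -> np.ndarray:
    """The 21-value C/T/D block of one property partition.

    Layout: [C1, C2, C3, T12, T13, T23,
             D1_0..D1_4, D2_0..D2_4, D3_0..D3_4].
    """
    L = len(seq)
    if L < 2:
        raise DomainError("CTD needs sequence length >= 2 (T uses adjacent pairs)")
    gmap = grouping.group_of()
    codes = np.array([gmap[c] for c in seq])

    comp = np.array([(codes == gi).sum() for gi in range(3)], dtype=float)
    comp = comp / L * 100.0

    a, b = codes[:-1], codes[1:]
    trans = np.zeros(3)
    for k, (i, j) in enumerate(((0, 1), (0, 2), (1, 2))):
        trans[k] = (((a == i) & (b == j)) | ((a == j) & (b == i))).sum()
    trans = trans / (L - 1) * 100.0

    dist = np.zeros((3, 5))
    for gi in range(3):
        positions = np.flatnonzero(codes == gi) + 1  # 1-based
        n = positions.size
        if n == 0:
            continue
        for j in range(5):
            p = 1 if j == 0 else max(1, (n * j) // 4)
            dist[gi, j] = positions[p - 1] / L * 100.0

    return np.concatenate([comp, trans, dist.ravel()])


def ctd_feature_names(grouping: PropertyGrouping) -> list[str]:
    p = grouping.property_name
    names = [f"{p}.C.{t}" for t in GROUP_TAGS]
    names += [f"{p}.T.{pair}" for pair in ("g1g2", "g1g3", "g2g3")]
    for t in GROUP_TAGS:
        names += [f"{p}.D.{t}.q{j}" for j in range(5)]
    return names


def extract_188(seq: str, groupings: GroupingSet = DEFAULT_GROUPINGS) -> np.ndarray:
    """The full 188D fingerprint: 20 composition + 8 x 21 CTD values."""
    parts = [aa_composition(seq)]
    parts += [ctd_for_property(seq, g) for g in groupings.groupings]
    vec = np.concatenate(parts)
    assert vec.size == 188
    return vec


def feature_names_188(groupings: GroupingSet = DEFAULT_GROUPINGS) -> list[str]:
    names = [f"comp.{a}" for a in AMINO_ALPHABET]
    for g in groupings.groupings:
        names += ctd_feature_names(g)
    return names


def extract_188_table(
    records: list[ProteinRecord],
    groupings: GroupingSet = DEFAULT_GROUPINGS,
    labels: list[str] | None = None,
) -> FeatureTable:
    """188D fingerprints for a batch of records as a :class:`FeatureTable`."""
    values = (
        np.vstack([extract_188(r.seq, groupings) for r in records])
        if records else np.empty((0, 188))
    )
    return FeatureTable(
        row_ids=[r.id for r in records],
        feature_names=feature_names_188(groupings),
        values=values,
        labels=labels,
    )
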
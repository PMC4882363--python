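"""Presence/absence atom-pair fingerprints and Tanimoto similarity.

An atom-pair feature is an unordered pair of atom descriptors — (element,
heavy-neighbor count, pi-electron count) — together with the topological
(shortest-path bond) distance between the two atoms.  A fingerprint is the
set of distinct features a molecule exhibits; multiplicity is discarded, so
these are market-basket items, not counts.

Features render to, and parse from, a stable human-readable string such as
``C [2 neighbor(s),1 pi electrons] <-3-> C [2 neighbor(s),1 pi electrons]``,
which is also the canonical serialization key.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable

from .molgraph import MolecularGraph, topological_distances

__all__ = [
    "AtomPairFeature",
    "Fingerprint",
    "atom_pairs",
    "render_feature",
    "parse_feature",
    "tanimoto_similarity",
    "tanimoto_distance",
]

Descriptor = tuple[str, int, int]  # (element, heavy_neighbors, pi_electrons)

DEFAULT_MAX_DISTANCE = 15


@dataclass(frozen=True, order=True)
class AtomPairFeature:
    """Unordered atom-descriptor pair at a fixed topological distance.

    The two descriptors are stored in canonical (lexicographic) order, so
    ``AtomPairFeature(a, b, d) == AtomPairFeature(b, a, d)``.
    """

    desc_a: Descriptor
    desc_b: Descriptor
    distance: int

    def __init__(self, desc_a: Descriptor, desc_b: Descriptor, distance: int):
        a, b = (tuple(desc_a), tuple(desc_b))
        if b < a:
            a, b = b, a
        if distance < 1:
            raise ValueError("distance must be >= 1")
        object.__setattr__(self, "desc_a", a)
        object.__setattr__(self, "desc_b", b)
        object.__setattr__(self, "distance", int(distance))

    def __str__(self) -> str:
        return render_feature(self)


@dataclass(frozen=True)
class Fingerprint:
    """Set of atom-pair features of one chemical."""

    id: str
    features: frozenset[AtomPairFeature] = field(default_factory=frozenset)

    def __len__(self) -> int:
        return len(self.features)

    def __contains__(self, feature: AtomPairFeature) -> bool:
        return feature in self.features

    def rendered(self) -> list[str]:
        """Sorted rendered feature strings (the JSON serialization form)."""
        return sorted(render_feature(f) for f in self.features)


def atom_pairs(g: MolecularGraph, max_distance: int = DEFAULT_MAX_DISTANCE) -> Fingerprint:
    """Atom-pair fingerprint of a connected molecular graph.

    One feature per distinct (descriptor, descriptor, distance) triple over
    all unordered atom pairs with shortest-path distance in
    ``[1, max_distance]``.  Single-heavy-atom molecules yield an empty
    fingerprint.
    """
    if max_distance < 1:
        raise ValueError("max_distance must be >= 1")
    if g.n_atoms < 2:
        return Fingerprint(id=g.id)
    dist = topological_distances(g)
    descs = [(a.element, a.heavy_neighbors, a.pi_electrons) for a in g.atoms]
    feats = set()
    for i, j in combinations(range(g.n_atoms), 2):
        d = dist[(i, j)]
        if 1 <= d <= max_distance:
            feats.add(AtomPairFeature(descs[i], descs[j], d))
    return Fingerprint(id=g.id, features=frozenset(feats))


def render_feature(f: AtomPairFeature) -> str:
    """Render a feature in the human-readable atom-pair style."""
    ea, na, pa = f.desc_a
    eb, nb, pb = f.desc_b
    return (
        f"{ea} [{na} neighbor(s),{pa} pi electrons] "
        f"<-{f.distance}-> "
        f"{eb} [{nb} neighbor(s),{pb} pi electrons]"
    )


_FEATURE_RE = re.compile(
    r"^\s*([A-Z][a-z]?)\s*\[(\d+) neighbor\(s\),(\d+) pi electrons\]\s*"
    r"<-(\d+)->\s*"
    r"([A-Z][a-z]?)\s*\[(\d+) neighbor\(s\),(\d+) pi electrons\]\s*$"
)


def parse_feature(text: str) -> AtomPairFeature:
    """Inverse of :func:`render_feature`."""
    m = _FEATURE_RE.match(text)
    if not m:
        raise ValueError(f"unparsable atom-pair feature: {text!r}")
    ea, na, pa, d, eb, nb, pb = m.groups()
    return AtomPairFeature((ea, int(na), int(pa)), (eb, int(nb), int(pb)), int(d))


def tanimoto_similarity(a: Fingerprint | frozenset, b: Fingerprint | frozenset) -> float:
    """Tanimoto (Jaccard) similarity |A∩B| / |A∪B| of two feature sets.

    Undefined (raises ValueError) when both sets are empty.
    """
    sa = a.features if isinstance(a, Fingerprint) else frozenset(a)
    sb = b.features if isinstance(b, Fingerprint) else frozenset(b)
    union = len(sa | sb)
    if union == 0:
        raise ValueError("Tanimoto similarity undefined for two empty fingerprints")
    return len(sa & sb) / union


def tanimoto_distance(a: Fingerprint | frozenset, b: Fingerprint | frozenset) -> float:
    """1 − Tanimoto similarity (a metric on sets)."""
    return 1.0 - tanimoto_similarity(a, b)


def fingerprints_to_json(fps: Iterable[Fingerprint]) -> dict[str, list[str]]:
    return {fp.id: fp.rendered() for fp in fps}


def fingerprints_from_json(obj: dict[str, list[str]]) -> dict[str, Fingerprint]:
    return {
        cid: Fingerprint(id=cid, features=frozenset(parse_feature(s) for s in feats))
        for cid, feats in obj.items()
    }
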
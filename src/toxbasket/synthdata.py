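"""Synthetic hazard datasets with planted, category-associated substructures.

The generator emulates a small acute-fish-toxicity screening table: a few
dozen small organic molecules built from a fixed library of aromatic,
heteroaromatic and aliphatic scaffolds, each decorated with the substructure
motif planted for its GHS category (with probability = ``fidelity``) or a
neutral decoy fragment otherwise.  Motifs are chemically distinctive
(dichloromethyl, nitro, nitrile, difluoromethyl by default) so their
internal atom pairs co-occur with their category at high conditional
probability — exactly the structure the rule miner is meant to recover.
LC50 values are drawn log-uniformly inside the target category's GHS band,
so they re-discretize to the assigned category exactly.

Everything is deterministic given the seed; the same config yields a
byte-identical CSV.

``generate_transactions`` produces abstract random baskets (no chemistry)
for exercising the miner against a brute-force oracle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .fingerprint import AtomPairFeature, atom_pairs, render_feature
from .hazard import CATEGORIES, HazardRecord, ghs_category, write_hazard_csv
from .molgraph import parse_smiles

__all__ = ["SynthConfig", "SynthDataset", "generate_dataset", "generate_transactions"]

# scaffold SMILES are written so that appending a fragment attaches it to the
# last-written atom (e.g. "c1ccccc1" + "[N+](=O)[O-]" -> nitrobenzene) and
# prepending one attaches it to the first; aromatic and aliphatic scaffolds
# alternate so that decoration cycles never align a structural class with a
# single category
SCAFFOLDS: tuple[str, ...] = (
    "c1ccccc1",      # benzene
    "C1CCCC1",       # cyclopentane
    "c1ccncc1",      # pyridine
    "C1CCCCC1",      # cyclohexane
    "c1cncnc1",      # pyrimidine
    "C1CCOC1",       # tetrahydrofuran
    "c1cc[nH]c1",    # pyrrole
    "C1CCOCC1",      # tetrahydropyran
    "c1ccoc1",       # furan
    "C1CCSC1",       # tetrahydrothiophene
    "c1ccsc1",       # thiophene
    "CCOCC",         # diethyl ether
    "Cc1ccoc1",      # methylfuran
    "CCSCC",         # diethyl sulfide
    "c1ocnc1",       # oxazole
    "CC(C)CC",       # 2-methylbutane
)

# prefix decorations that individualize repeated scaffold/motif combinations
VARIANTS: tuple[str, ...] = ("", "C", "CC", "CCC", "CO", "COC", "CC(C)")

DEFAULT_MOTIFS: dict[str, str] = {
    "CAT1": "C(Cl)Cl",
    "CAT2": "[N+](=O)[O-]",
    "CAT3": "C#N",
    "CAT4": "C(F)F",
}

# equivalent SMILES of each built-in motif written as a prefix, used when a
# chemical carries its motif on the decoration side instead of the scaffold
# tail; custom motifs without a prefix form always attach at the tail
MOTIF_PREFIX_FORMS: dict[str, str] = {
    "C(Cl)Cl": "ClC(Cl)",
    "[N+](=O)[O-]": "O=[N+]([O-])",
    "C#N": "N#C",
    "C(F)F": "FC(F)",
}

DECOYS: tuple[str, ...] = ("C", "CC", "OCC")

# log10 LC50 band per category (upper bounds inclusive)
_LOG_BANDS = {"CAT1": (-3.0, 0.0), "CAT2": (0.0, 1.0), "CAT3": (1.0, 2.0), "CAT4": (2.0, 3.0)}


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions of a synthetic dataset."""

    n_chemicals: int = 60
    mix: tuple[float, float, float, float] = (0.10, 0.30, 0.40, 0.20)
    motifs: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_MOTIFS))
    fidelity: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chemicals < 1:
            raise ValueError("n_chemicals must be >= 1")
        if len(self.mix) != 4 or any(p < 0 for p in self.mix):
            raise ValueError("mix must be four non-negative proportions")
        if abs(sum(self.mix) - 1.0) > 1e-9:
            raise ValueError(f"mix must sum to 1, got {sum(self.mix)}")
        if not (0.5 < self.fidelity <= 1.0):
            raise ValueError("fidelity must be in (0.5, 1]")
        for cat in self.motifs:
            if cat not in CATEGORIES:
                raise ValueError(f"unknown category {cat!r} in motifs")
        for cat, p in zip(CATEGORIES, self.mix):
            if cat in self.motifs and p == 0.0:
                raise ValueError(
                    f"category {cat} has a planted motif but zero proportion"
                )


@dataclass
class SynthDataset:
    """Generated records plus the planted ground truth."""

    records: list[HazardRecord]
    motif_features: dict[str, frozenset[AtomPairFeature]]
    config: SynthConfig

    def write_csv(self, path: str | Path) -> None:
        write_hazard_csv(self.records, path)

    def write_ground_truth(self, path: str | Path) -> None:
        obj = {
            "motif_smiles": dict(self.config.motifs),
            "motif_features": {
                cat: sorted(render_feature(f) for f in feats)
                for cat, feats in self.motif_features.items()
            },
            "fidelity": self.config.fidelity,
            "seed": self.config.seed,
        }
        Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def largest_remainder_counts(n: int, proportions: Sequence[float]) -> list[int]:
    """Allocate n into integer counts matching proportions (largest remainder)."""
    quotas = [n * p for p in proportions]
    counts = [int(q) for q in quotas]
    short = n - sum(counts)
    remainders = sorted(
        range(len(proportions)), key=lambda i: (-(quotas[i] - counts[i]), i)
    )
    for i in remainders[:short]:
        counts[i] += 1
    return counts


def generate_dataset(cfg: SynthConfig = SynthConfig()) -> SynthDataset:
    """Generate a synthetic hazard dataset with planted toxicophores.

    Each chemical is a decorated scaffold carrying its category's planted
    motif with probability ``cfg.fidelity`` and a decoy fragment otherwise.
    The context — scaffold, decoration, attachment side — cycles through the
    same sequence in every category, so generic (non-motif) substructure
    combinations recur across categories and cannot form confident
    single-category rules on their own.  The returned motif table records,
    per category, the union over its chemicals of the atom-pair features the
    motif actually introduces (fingerprint with motif minus fingerprint
    without).
    """
    rng = np.random.default_rng(cfg.seed)
    counts = largest_remainder_counts(cfg.n_chemicals, cfg.mix)

    records: list[HazardRecord] = []
    motif_features: dict[str, set[AtomPairFeature]] = {
        cat: set() for cat in cfg.motifs
    }
    chem_no = 0
    for ci, (cat, count) in enumerate(zip(CATEGORIES, counts)):
        lo, hi = _LOG_BANDS[cat]
        for j in range(count):
            cid = f"syn{chem_no:03d}"
            chem_no += 1
            # context (scaffold, decoration, attachment side) depends only on
            # the within-category index, so the same context sequence recurs
            # in every category: generic substructure combinations therefore
            # span categories and only motif-derived atom pairs can align
            # with a single category
            scaffold = SCAFFOLDS[(3 * j) % len(SCAFFOLDS)]
            variant = VARIANTS[j % len(VARIANTS)]
            base = variant + scaffold

            planted = cat in cfg.motifs and rng.random() < cfg.fidelity
            fragment = cfg.motifs[cat] if planted else DECOYS[rng.integers(len(DECOYS))]
            # alternate the attachment side so cross-distances vary between
            # chemicals sharing a scaffold or decoration
            head = (j // 2) % 2 == 1 and fragment in MOTIF_PREFIX_FORMS
            smiles = MOTIF_PREFIX_FORMS[fragment] + base if head else base + fragment

            # keep strictly inside the open lower bound of the band
            u = 0.001 + 0.999 * rng.random()
            lc50 = float(10.0 ** (lo + u * (hi - lo)))
            assert ghs_category(lc50) == cat

            records.append(HazardRecord(cid, smiles, lc50, cat))
            if planted:
                with_motif = atom_pairs(parse_smiles(smiles, cid)).features
                without = atom_pairs(parse_smiles(base, cid + "_base")).features
                motif_features[cat] |= with_motif - without

    return SynthDataset(
        records=records,
        motif_features={cat: frozenset(v) for cat, v in motif_features.items()},
        config=cfg,
    )


def generate_transactions(
    n_txns: int, n_items: int, density: float, seed: int
) -> list[frozenset]:
    """Random abstract baskets: each of ``n_items`` labeled items is present
    in each transaction independently with probability ``density``."""
    if not (0 < density <= 1):
        raise ValueError("density must be in (0, 1]")
    rng = np.random.default_rng(seed)
    items = [f"i{k:02d}" for k in range(n_items)]
    mask = rng.random((n_txns, n_items)) < density
    return [
        frozenset(items[k] for k in range(n_items) if mask[t, k])
        for t in range(n_txns)
    ]
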
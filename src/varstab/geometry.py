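"""C-alpha geometry: spatial clustering of affected positions.

Measures whether a set of variant positions sits closer together in the
folded structure than same-size random position sets from the same domain,
via the mean pairwise C-alpha distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist

__all__ = [
    "CoordinateSet",
    "read_calpha",
    "mean_pairwise_distance",
    "random_baseline",
]


@dataclass
class CoordinateSet:
    """Residue position (1-based) -> C-alpha coordinates in Angstrom."""

    coords: dict[int, np.ndarray]
    chain: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        for pos, xyz in self.coords.items():
            arr = np.asarray(xyz, dtype=float)
            if arr.shape != (3,) or not np.all(np.isfinite(arr)):
                raise ValueError(f"bad coordinates at position {pos}")
            self.coords[pos] = arr

    @property
    def positions(self) -> list[int]:
        return sorted(self.coords)


def read_calpha(path: str | Path, chain: str, model_index: int = 0) -> CoordinateSet:
    """Extract one C-alpha per residue from a PDB file.

    Altloc conflicts resolve to the highest occupancy (first-listed on
    ties); residues lacking a C-alpha are skipped with a single warning
    giving the count.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(path))
    models = list(structure)
    if model_index >= len(models):
        raise ValueError(f"model {model_index} not present in {path}")
    model = models[model_index]
    chain_ids = [c.id for c in model]
    if chain not in chain_ids:
        raise KeyError(f"chain {chain!r} not found; available: {chain_ids}")
    coords: dict[int, np.ndarray] = {}
    n_missing = 0
    for residue in model[chain]:
        hetflag, resseq, _icode = residue.id
        if hetflag.strip():
            continue
        if "CA" not in residue:
            n_missing += 1
            continue
        atom = residue["CA"]
        if atom.is_disordered():
            # highest occupancy; Bio.PDB orders altlocs as listed, so a
            # stable max keeps the first-listed on ties
            alts = list(atom)
            best = max(alts, key=lambda a: (a.get_occupancy() or 0.0))
            coords[resseq] = np.array(best.get_coord(), dtype=float)
        else:
            coords[resseq] = np.array(atom.get_coord(), dtype=float)
    if n_missing:
        warnings.warn(f"{path}: skipped {n_missing} residues lacking a C-alpha")
    if not coords:
        raise ValueError(f"chain {chain!r} in {path} has no C-alpha atoms")
    return CoordinateSet(coords=coords, chain=chain, source=str(path))


def mean_pairwise_distance(positions: Sequence[int], coords: CoordinateSet) -> float:
    """Mean Euclidean distance over all unordered position pairs."""
    positions = list(positions)
    if len(set(positions)) != len(positions):
        raise ValueError("duplicate positions in input")
    if len(positions) < 2:
        raise ValueError("need at least 2 positions")
    missing = [p for p in positions if p not in coords.coords]
    if missing:
        raise KeyError(f"positions missing coordinates: {missing}")
    pts = np.stack([coords.coords[p] for p in positions])
    return float(pdist(pts).mean())


def random_baseline(
    domain_positions: Sequence[int],
    k: int,
    n_samples: int,
    seed: int,
    coords: CoordinateSet,
) -> float:
    """Mean pairwise distance of random k-subsets of the domain.

    Uniform subsets without replacement, averaged over ``n_samples``
    draws; fully determined by ``seed``.
    """
    domain_positions = list(domain_positions)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(domain_positions):
        raise ValueError("k exceeds the number of domain positions")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    values = []
    for _ in range(n_samples):
        subset = rng.choice(domain_positions, size=k, replace=False)
        values.append(mean_pairwise_distance(subset.tolist(), coords))
    return float(np.mean(values))


def exhaustive_baseline(
    domain_positions: Sequence[int], k: int, coords: CoordinateSet
) -> float:
    """Exact all-subsets average (small instances only)."""
    vals = [
        mean_pairwise_distance(list(sub), coords)
        for sub in combinations(domain_positions, k)
    ]
    return float(np.mean(vals))
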
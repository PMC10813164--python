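"""Product chemistry: circular fingerprints, Dice similarity, skeletons.

Product similarity between two enzymes is the mean Dice coefficient over
the full cross-product of their products' Morgan (ECFP4-equivalent,
radius 2) bit fingerprints — a single-product pair reduces to one value.
The carbon-skeleton reduction (drop heteroatoms and stereocentres, saturate
all bonds, keep the largest carbon component) groups products the way
diterpene skeleton classes (labdane, kaurane, ...) are defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator

from .io_model import EnzymeRecord
from .seq_analysis import SimilarityMatrix

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "Fingerprint",
    "fingerprint",
    "dice",
    "product_similarity",
    "product_similarity_matrix",
    "skeletonize",
]

DEFAULT_RADIUS = 2
DEFAULT_NBITS = 2048

_GENERATORS: dict[tuple[int, int], object] = {}


def _generator(radius: int, n_bits: int):
    key = (radius, n_bits)
    if key not in _GENERATORS:
        _GENERATORS[key] = rdFingerprintGenerator.GetMorganGenerator(
            radius=radius, fpSize=n_bits
        )
    return _GENERATORS[key]


@dataclass(frozen=True)
class Fingerprint:
    """A folded circular (Morgan/ECFP) bit fingerprint."""

    bits: frozenset[int]
    radius: int = DEFAULT_RADIUS
    n_bits: int = DEFAULT_NBITS

    def __post_init__(self) -> None:
        if any(not (0 <= b < self.n_bits) for b in self.bits):
            raise ValueError("bit positions outside [0, n_bits)")


def fingerprint(
    smiles: str, radius: int = DEFAULT_RADIUS, n_bits: int = DEFAULT_NBITS
) -> Fingerprint:
    """Morgan fingerprint of a SMILES string (radius 2, 2048 bits by default)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    fp = _generator(radius, n_bits).GetFingerprint(mol)
    return Fingerprint(
        bits=frozenset(fp.GetOnBits()), radius=radius, n_bits=n_bits
    )


def dice(a: Fingerprint, b: Fingerprint) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A| + |B|) of two fingerprints."""
    if a.n_bits != b.n_bits:
        raise ValueError(f"fingerprint widths differ: {a.n_bits} vs {b.n_bits}")
    if not a.bits and not b.bits:
        warnings.warn("Dice of two empty fingerprints defined as 0")
        return 0.0
    return 2.0 * len(a.bits & b.bits) / (len(a.bits) + len(b.bits))


def _record_fps(record: EnzymeRecord, radius: int, n_bits: int) -> list[Fingerprint]:
    fps = []
    for p in record.products:
        if not p.parseable:
            continue
        try:
            fps.append(fingerprint(p.smiles, radius, n_bits))
        except ValueError:
            continue
    return fps


def product_similarity(
    a: EnzymeRecord,
    b: EnzymeRecord,
    radius: int = DEFAULT_RADIUS,
    n_bits: int = DEFAULT_NBITS,
) -> float:
    """Mean Dice over the full cross-product of the two enzymes' products."""
    fa = _record_fps(a, radius, n_bits)
    fb = _record_fps(b, radius, n_bits)
    missing = [r.accession for r, f in ((a, fa), (b, fb)) if not f]
    if missing:
        raise ValueError(f"no valid products for: {missing}")
    return float(np.mean([dice(x, y) for x in fa for y in fb]))


def product_similarity_matrix(
    records: Sequence[EnzymeRecord],
    radius: int = DEFAULT_RADIUS,
    n_bits: int = DEFAULT_NBITS,
) -> SimilarityMatrix:
    """Pairwise product-similarity matrix (kind ``product_dsc``).

    The diagonal is computed like any pair — the self cross-product of a
    multi-product enzyme with dissimilar products is below 1 — and is
    excluded from all downstream correlations.
    """
    fps = {r.accession: _record_fps(r, radius, n_bits) for r in records}
    missing = [acc for acc, f in fps.items() if not f]
    if missing:
        raise ValueError(f"no valid products for: {missing}")
    ids = [r.accession for r in records]
    n = len(ids)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            v = float(
                np.mean([dice(x, y) for x in fps[ids[i]] for y in fps[ids[j]]])
            )
            vals[i, j] = vals[j, i] = v
    return SimilarityMatrix(ids=ids, values=vals, kind="product_dsc", scale="unit")


def skeletonize(smiles: str) -> str:
    """Canonical carbon skeleton of a molecule.

    Removes all heteroatoms and stereocentres, reduces every bond to a
    single bond, keeps the largest connected carbon component, and returns
    its canonical SMILES.  Two products share a skeleton class iff their
    skeletons are equal strings.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    em = Chem.RWMol()
    idx_map: dict[int, int] = {}
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 6:
            a = Chem.Atom(6)
            idx_map[atom.GetIdx()] = em.AddAtom(a)
    if not idx_map:
        raise ValueError(f"no carbon atoms in {smiles!r}")
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if i in idx_map and j in idx_map:
            em.AddBond(idx_map[i], idx_map[j], Chem.BondType.SINGLE)
    skel = em.GetMol()
    Chem.SanitizeMol(skel)
    frags = Chem.GetMolFrags(skel, asMols=True)
    largest = max(frags, key=lambda m: m.GetNumAtoms())
    return Chem.MolToSmiles(largest)
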
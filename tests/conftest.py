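import numpy as np
import pytest

from ditps3d.io_model import Atom, Residue, StructureModel
from ditps3d.synthetic_data import CohortConfig, build_cohort, motif_benchmark_config


@pytest.fixture(scope="session")
def cohort():
    """Default three-family cohort with structures (seed 1)."""
    return build_cohort(CohortConfig(seed=1))


@pytest.fixture(scope="session")
def bench_cohort():
    """Single-family planted-motif benchmark cohort (seed 0)."""
    return build_cohort(motif_benchmark_config(0))


def make_ca_structure(coords, sid="toy", letters=None):
    """Structure with CA-only residues at the given coordinates."""
    coords = np.asarray(coords, float)
    letters = letters or "A" * len(coords)
    three = {
        "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
        "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
        "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
        "W": "TRP", "Y": "TYR",
    }
    residues = [
        Residue("A", i + 1, three[l], (Atom("CA", "C", tuple(c)),))
        for i, (c, l) in enumerate(zip(coords, letters))
    ]
    return StructureModel(sid, residues)


def random_walk(rng, n, step=3.8, min_sep=3.0):
    """Self-avoiding random chain used for toy structures."""
    pts = [np.zeros(3)]
    while len(pts) < n:
        d = rng.normal(size=3)
        cand = pts[-1] + step * d / np.linalg.norm(d)
        if all(np.linalg.norm(cand - p) > min_sep for p in pts[:-1]):
            pts.append(cand)
    return np.array(pts)
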
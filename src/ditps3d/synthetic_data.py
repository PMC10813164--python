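"""Deterministic generator of a toy diterpene-synthase cohort.

The generator emulates exactly the features of the curated real dataset the
pipeline consumes, with known ground truth for recovery tests:

* **Structures** — one PDB per enzyme: a self-avoiding C-alpha-trace
  backbone (3.8 A steps, glycine-like N/CA/C/O atom stubs) kept clear of
  the pocket, a ligand HETATM block at the pocket centroid, and a planted
  active-site motif whose residues sit at fixed template coordinates plus
  isotropic Gaussian jitter (sigma 0.3 A per axis by default), surrounded
  by per-enzyme random decoy residues.  Chain continuity is deliberately
  broken where pocket residues interleave the backbone: every downstream
  computation is geometric over atom distances, not energetic.
* **Sequences** — family-specific random backgrounds (alphabet without D,
  so aspartate motifs occur only where planted) with per-enzyme point
  mutations, class signature motifs (DXDD and/or DDXXD) embedded per the
  configured class mix, and pocket residue letters written at the pocket
  sequence positions.
* **Products** — each family draws from a disjoint SMILES sub-library of a
  distinct diterpene-like scaffold; a per-enzyme "defection" probability
  re-assigns the product family, which tunes the planted correlation
  between sequence similarity and product similarity (see
  ``COUPLING_DEFECT_RATE``); a shared bridge molecule softens
  between-family dissimilarity.
* **Held-out sites** — one designated enzyme per family carries a single
  substitution at a motif position, the target for relaxed motif search.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio.SeqUtils import seq3
import gemmi

from .io_model import (
    Atom,
    ClassLabel,
    EnzymeRecord,
    LigandPose,
    ProductRef,
    Residue,
    StructureModel,
    write_annotation,
)
from .seq_analysis import classify_class

__all__ = [
    "CohortConfig",
    "CohortTruth",
    "Cohort",
    "build_cohort",
    "generate_cohort",
    "load_truth",
    "truth_check",
    "motif_benchmark_config",
    "coupling_benchmark_config",
]

# default planted active-site motif: conserved residues named in the
# terpene-synthase literature (aspartate, aromatics, Ser/Arg)
MOTIF_LETTERS = ("D", "W", "F", "Y", "S", "R")
# irregular template C-alpha coordinates (A) around the ligand centroid;
# deliberately asymmetric so the motif has a unique geometric placement
MOTIF_TEMPLATE = np.array(
    [
        [4.6, -1.5, -1.5],
        [-2.5, 3.6, 1.0],
        [1.5, -4.3, 1.2],
        [3.0, 2.8, 2.6],
        [-1.0, -2.0, -4.2],
        [-4.4, -1.2, -1.0],
    ]
)
# ligand heavy atoms (a GGPP-like stub): 4 carbons + 1 phosphorus
LIGAND_ATOMS = [
    ("C1", "C", (-2.0, 0.0, 0.0)),
    ("C2", "C", (-0.7, 0.6, 0.0)),
    ("C3", "C", (0.7, -0.6, 0.0)),
    ("C4", "C", (2.0, 0.0, 0.0)),
    ("P1", "P", (3.2, 0.8, 0.0)),
]
LIGAND_CODE = "GGP"

BACKGROUND_ALPHABET = "ACEFGHIKLMNPQRSTVWY"  # 19 letters, no aspartate
CLASS_I_MOTIF = "DDLID"  # DDXXD spelling
CLASS_II_MOTIF = "DLDD"  # DXDD spelling

# product sub-libraries: distinct scaffolds per family (within-family Dice
# ~0.5-0.8, between-family ~0.1-0.4)
PRODUCT_LIBRARIES: dict[str, list[tuple[str, str]]] = {
    "linear": [
        ("geranylgeraniol", "CC(C)=CCCC(C)=CCCC(C)=CCCC(C)=CCO"),
        ("tetraprenene", "CC(C)=CCCC(C)=CCCC(C)=CCCC(C)=CC"),
        ("dihydrogeranylgeraniol", "CC(C)CCCC(C)=CCCC(C)=CCCC(C)=CCO"),
    ],
    "labdane": [
        ("labdatriene", "CC1(C)CCCC2(C)C1CCC1(C)C2CCC1C(C)=C"),
        ("labdanol", "CC1(C)CCCC2(C)C1CCC(C(C)=C)C2O"),
        ("labdane-core", "CC1(C)CCCC2(C)C1CCC(C(C)C)C2"),
    ],
    "abietane": [
        ("abietatriene", "CC(C)c1ccc2c(c1)CCC1C(C)(C)CCCC21C"),
        ("nor-abietatriene", "CC(C)c1ccc2c(c1)CCC1C(C)(C)CCCC21"),
        ("hydroxyabietatriene", "CC(C)c1cc2c(cc1O)CCC1C(C)(C)CCCC21C"),
    ],
}
BRIDGE_PRODUCT = ("monocyclogeranylgeraniol", "CC(C)=CCCC(C)=CCC1CCCC(C)(C)C1")

#: Fraction of enzymes (exactly round(rate * n), chosen at random) that draw
#: products from a foreign family library.  This knob sets the planted
#: correlation between sequence identity and product Dice similarity; the
#: default was calibrated once by brute-force simulation to a target pairwise
#: correlation of 0.5 at 50 enzymes.
COUPLING_DEFECT_RATE = 0.16
#: Probability of adding the shared bridge molecule to an enzyme's products.
BRIDGE_RATE = 0.10


@dataclass
class CohortConfig:
    """Study conditions of the synthetic cohort."""

    n_enzymes: int = 18
    n_families: int = 3
    chain_length: int = 80
    motif_letters: tuple[str, ...] = MOTIF_LETTERS
    motif_template: np.ndarray = field(default_factory=lambda: MOTIF_TEMPLATE.copy())
    jitter_sigma_A: float = 0.3
    n_decoys: int = 2
    n_family_pocket: int = 2
    class_mix: dict[str, float] = field(
        default_factory=lambda: {"I": 0.4, "II": 0.35, "I/II": 0.25}
    )
    mutation_rate: float = 0.08
    coupling_defect_rate: float = COUPLING_DEFECT_RATE
    bridge_rate: float = BRIDGE_RATE
    held_out_per_family: int = 1
    with_structures: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.motif_letters) < 3:
            raise ValueError("planted motif needs >= 3 residues")
        if abs(sum(self.class_mix.values()) - 1.0) > 1e-9:
            raise ValueError("class_mix proportions must sum to 1")
        if self.n_enzymes < self.n_families:
            raise ValueError("need at least one enzyme per family")


@dataclass
class CohortTruth:
    """Ground truth emitted alongside the cohort files."""

    seed: int
    target_rho: float
    families: dict[str, int]
    class_labels: dict[str, str]
    pocket_positions: dict[str, list[int]]  # planted motif residue numbers
    held_out: list[str]
    mutated_position: dict[str, int]  # held-out accession -> residue number
    product_family: dict[str, str]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2), encoding="utf-8")


def load_truth(path: str | Path) -> CohortTruth:
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    return CohortTruth(**data)


@dataclass
class Cohort:
    """In-memory synthetic cohort."""

    records: list[EnzymeRecord]
    structures: dict[str, StructureModel]
    ligands: dict[str, LigandPose]
    truth: CohortTruth


# ---------------------------------------------------------------------------
# helpers


def _pocket_sequence_positions(
    length: int, k: int, forbidden: list[tuple[int, int]]
) -> list[int]:
    """k well-spread 1-based positions avoiding the forbidden windows."""
    out: list[int] = []
    candidates = np.linspace(6, length - 6, num=4 * k).round().astype(int)
    for pos in candidates:
        pos = int(pos)
        if any(a - 3 <= pos <= b + 3 for a, b in forbidden):
            continue
        if any(abs(pos - p) < 4 for p in out):
            continue
        out.append(pos)
        if len(out) == k:
            return out
    raise ValueError("cannot place pocket residues: sequence too short")


def _self_avoiding_walk(
    rng: np.random.Generator, n_steps: int, keep_out_radius: float = 11.5
) -> np.ndarray:
    """Backbone C-alpha trace: 3.8 A steps, self-avoiding, clear of the pocket."""
    for _attempt in range(1000):
        direction = rng.normal(size=3)
        start = (keep_out_radius + 2.5) * direction / np.linalg.norm(direction)
        pts = [start]
        ok = True
        while len(pts) < n_steps:
            placed = False
            for _try in range(200):
                step = rng.normal(size=3)
                step = 3.8 * step / np.linalg.norm(step)
                cand = pts[-1] + step
                if np.linalg.norm(cand) < keep_out_radius or np.linalg.norm(cand) > 45:
                    continue
                d = np.linalg.norm(np.array(pts[:-1]) - cand, axis=1) if len(pts) > 1 else [9.9]
                if np.min(d) < 3.4:
                    continue
                pts.append(cand)
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            return np.array(pts)
    raise RuntimeError(f"infeasible backbone geometry after 1000 attempts")


_STUB_OFFSETS = {
    "N": np.array([-1.20, 0.80, 0.00]),
    "C": np.array([1.25, 0.75, 0.00]),
    "O": np.array([1.85, 1.80, 0.00]),
}


def _make_residue(chain: str, number: int, letter: str, ca: np.ndarray) -> Residue:
    name = seq3(letter).upper()
    atoms = [Atom("N", "N", tuple(ca + _STUB_OFFSETS["N"]))]
    atoms.append(Atom("CA", "C", tuple(ca)))
    atoms.append(Atom("C", "C", tuple(ca + _STUB_OFFSETS["C"])))
    atoms.append(Atom("O", "O", tuple(ca + _STUB_OFFSETS["O"])))
    return Residue(chain, number, name, tuple(atoms))


def _random_sphere_point(rng: np.random.Generator, rmin: float, rmax: float) -> np.ndarray:
    v = rng.normal(size=3)
    v /= np.linalg.norm(v)
    return v * rng.uniform(rmin, rmax)


CA_MIN_SEPARATION = 2.8  # steric exclusion between pocket C-alphas (A)


def _place_pocket_points(
    rng: np.random.Generator,
    n: int,
    rmin: float,
    rmax: float,
    occupied: np.ndarray,
) -> np.ndarray:
    """Random pocket points keeping C-alpha steric separation from ``occupied``."""
    placed: list[np.ndarray] = []
    for _ in range(n):
        for _try in range(500):
            p = _random_sphere_point(rng, rmin, rmax)
            others = occupied if not placed else np.vstack([occupied, placed])
            if np.linalg.norm(others - p, axis=1).min() >= CA_MIN_SEPARATION:
                placed.append(p)
                break
        else:
            raise RuntimeError("infeasible pocket geometry after 500 attempts")
    return np.array(placed) if placed else np.empty((0, 3))


def _assign_classes(n: int, mix: dict[str, float], rng: np.random.Generator) -> list[str]:
    labels = list(mix)
    counts = {l: int(round(mix[l] * n)) for l in labels}
    while sum(counts.values()) < n:
        counts[labels[0]] += 1
    while sum(counts.values()) > n:
        counts[max(labels, key=lambda l: counts[l])] -= 1
    seq = [l for l in labels for _ in range(counts[l])]
    rng.shuffle(seq)
    return seq


# ---------------------------------------------------------------------------
# cohort construction


def build_cohort(config: CohortConfig) -> Cohort:
    """Generate the cohort in memory (deterministic in ``config.seed``)."""
    rng = np.random.default_rng(config.seed)
    n_fam = config.n_families
    length = config.chain_length
    fam_names = list(PRODUCT_LIBRARIES)
    if n_fam > len(fam_names):
        fam_names = fam_names + [f"family{i}" for i in range(len(fam_names), n_fam)]

    # class signature windows (1-based)
    ii_start = max(2, int(round(0.30 * length)))
    i_start = int(round(0.75 * length))
    forbidden = [
        (ii_start, ii_start + len(CLASS_II_MOTIF) - 1),
        (i_start, i_start + len(CLASS_I_MOTIF) - 1),
    ]
    k_motif = len(config.motif_letters)
    k_pocket = k_motif + config.n_decoys + config.n_family_pocket
    pocket_pos = _pocket_sequence_positions(length, k_pocket, forbidden)
    motif_pos = pocket_pos[:k_motif]
    decoy_pos = pocket_pos[k_motif : k_motif + config.n_decoys]
    fam_pos = pocket_pos[k_motif + config.n_decoys :]

    # family-level draws
    bg = [rng.choice(list(BACKGROUND_ALPHABET), size=length) for _ in range(n_fam)]
    fam_pocket_letters = [
        rng.choice(list("KNQMTH"), size=config.n_family_pocket) for _ in range(n_fam)
    ]
    fam_pocket_coords = [
        _place_pocket_points(rng, config.n_family_pocket, 5.0, 5.8, config.motif_template)
        for _ in range(n_fam)
    ]

    classes = _assign_classes(config.n_enzymes, config.class_mix, rng)
    # fixed defector count (round(rate * n)) rather than per-enzyme coin
    # flips: pins the planted sequence-product coupling tightly to its target
    n_defect = int(round(config.coupling_defect_rate * config.n_enzymes))
    defectors = (
        set(rng.choice(config.n_enzymes, size=n_defect, replace=False).tolist())
        if n_fam > 1 and n_defect
        else set()
    )
    fam_members: dict[int, list[int]] = {f: [] for f in range(n_fam)}
    for i in range(config.n_enzymes):
        fam_members[i % n_fam].append(i)
    held_out_idx: set[int] = set()
    for f in range(n_fam):
        held_out_idx |= set(fam_members[f][-config.held_out_per_family :])

    records: list[EnzymeRecord] = []
    structures: dict[str, StructureModel] = {}
    ligands: dict[str, LigandPose] = {}
    truth = CohortTruth(
        seed=config.seed,
        target_rho=0.5,
        families={},
        class_labels={},
        pocket_positions={},
        held_out=[],
        mutated_position={},
        product_family={},
    )

    for i in range(config.n_enzymes):
        fam = i % n_fam
        acc = f"SYN{i:03d}"
        label = classes[i]
        is_held_out = i in held_out_idx

        # ---- sequence
        for _try in range(50):
            letters = bg[fam].copy()
            mutate = rng.random(length) < config.mutation_rate
            letters[mutate] = rng.choice(list(BACKGROUND_ALPHABET), size=int(mutate.sum()))
            if label in ("II", "I/II"):
                letters[ii_start - 1 : ii_start - 1 + len(CLASS_II_MOTIF)] = list(CLASS_II_MOTIF)
            if label in ("I", "I/II"):
                letters[i_start - 1 : i_start - 1 + len(CLASS_I_MOTIF)] = list(CLASS_I_MOTIF)
            for p, l in zip(motif_pos, config.motif_letters):
                letters[p - 1] = l
            for p, l in zip(fam_pos, fam_pocket_letters[fam]):
                letters[p - 1] = l
            decoy_letters = rng.choice(list(BACKGROUND_ALPHABET), size=config.n_decoys)
            for p, l in zip(decoy_pos, decoy_letters):
                letters[p - 1] = l
            mutated_slot: int | None = None
            if is_held_out:
                slot = int(rng.integers(0, k_motif))
                letters[motif_pos[slot] - 1] = "A"
                mutated_slot = slot
            seq = "".join(letters)
            if classify_class(seq) is ClassLabel.parse(label):
                break
        else:
            raise RuntimeError(f"{acc}: could not realize class label {label}")

        # ---- structure
        if config.with_structures:
            motif_ca = config.motif_template + rng.normal(
                0.0, config.jitter_sigma_A, size=config.motif_template.shape
            )
            famres_ca = fam_pocket_coords[fam] + rng.normal(
                0.0, config.jitter_sigma_A, size=fam_pocket_coords[fam].shape
            )
            occupied = (
                np.vstack([motif_ca, famres_ca]) if len(famres_ca) else motif_ca
            )
            decoy_ca = _place_pocket_points(rng, config.n_decoys, 4.2, 6.8, occupied)
            n_backbone = length - k_pocket
            walk = _self_avoiding_walk(rng, n_backbone)
            ca_by_pos: dict[int, np.ndarray] = {}
            for p, c in zip(motif_pos, motif_ca):
                ca_by_pos[p] = c
            for p, c in zip(decoy_pos, decoy_ca):
                ca_by_pos[p] = c
            for p, c in zip(fam_pos, famres_ca):
                ca_by_pos[p] = c
            w = 0
            for p in range(1, length + 1):
                if p not in ca_by_pos:
                    ca_by_pos[p] = walk[w]
                    w += 1
            residues = [
                _make_residue("A", p, seq[p - 1], ca_by_pos[p]) for p in range(1, length + 1)
            ]
            structures[acc] = StructureModel(structure_id=acc, residues=residues)
            ligands[acc] = LigandPose(
                ligand_id=LIGAND_CODE,
                atoms=[Atom(n, e, xyz) for n, e, xyz in LIGAND_ATOMS],
            )

        # ---- products
        eff_fam = fam
        if i in defectors:
            others = [f for f in range(n_fam) if f != fam]
            eff_fam = int(rng.choice(others))
        lib = PRODUCT_LIBRARIES[fam_names[eff_fam % len(PRODUCT_LIBRARIES)]]
        n_prod = 1 if rng.random() < 0.3 else 2
        chosen = rng.choice(len(lib), size=min(n_prod, len(lib)), replace=False)
        products = [
            ProductRef(name=lib[c][0], smiles=lib[c][1], skeleton=fam_names[eff_fam])
            for c in sorted(chosen)
        ]
        if rng.random() < config.bridge_rate:
            products.append(
                ProductRef(name=BRIDGE_PRODUCT[0], smiles=BRIDGE_PRODUCT[1], skeleton="bridge")
            )

        substrate = "GGPP" if label in ("II", "I/II") else "ent-CPP"
        boundary = length // 2
        rec = EnzymeRecord(
            accession=acc,
            sequence=seq,
            class_label=ClassLabel.parse(label),
            species=f"Planta synthetica {fam_names[fam]}",
            lineage=(f"Synthfam{fam}", f"Genus{fam}"),
            domain_ranges={"N": (1, boundary), "C": (boundary + 1, length)},
            substrate=substrate,
            products=products,
        )
        records.append(rec)

        truth.families[acc] = fam
        truth.class_labels[acc] = label
        truth.pocket_positions[acc] = list(motif_pos)
        truth.product_family[acc] = fam_names[eff_fam % len(PRODUCT_LIBRARIES)]
        if is_held_out:
            truth.held_out.append(acc)
            truth.mutated_position[acc] = motif_pos[mutated_slot]

    return Cohort(records=records, structures=structures, ligands=ligands, truth=truth)


# ---------------------------------------------------------------------------
# file emission


def _write_structure_pdb(
    structure: StructureModel, ligand: LigandPose, path: Path
) -> None:
    st = gemmi.Structure()
    st.name = structure.structure_id
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for res in structure.residues:
        g = gemmi.Residue()
        g.name = res.name
        g.seqid = gemmi.SeqId(res.number, " ")
        g.het_flag = "A"
        for a in res.atoms:
            ga = gemmi.Atom()
            ga.name = a.name
            ga.element = gemmi.Element(a.element)
            ga.pos = gemmi.Position(*a.xyz)
            ga.occ = 1.0
            g.add_atom(ga)
        chain.add_residue(g)
    model.add_chain(chain)
    lig_chain = gemmi.Chain("L")
    lg = gemmi.Residue()
    lg.name = LIGAND_CODE
    lg.seqid = gemmi.SeqId(901, " ")
    lg.het_flag = "H"
    for a in ligand.atoms:
        ga = gemmi.Atom()
        ga.name = a.name
        ga.element = gemmi.Element(a.element)
        ga.pos = gemmi.Position(*a.xyz)
        ga.occ = 1.0
        lg.add_atom(ga)
    lig_chain.add_residue(lg)
    model.add_chain(lig_chain)
    st.add_model(model)
    Path(path).write_text(st.make_pdb_string(), encoding="utf-8")


def generate_cohort(config: CohortConfig, outdir: str | Path) -> CohortTruth:
    """Generate the cohort and write it to ``outdir``.

    Emits ``annotation.tsv``, ``sequences.fasta``, ``structures/*.pdb``
    (when structures are enabled), and ``truth.json``.  Byte-identical for
    a fixed config and seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = build_cohort(config)
    write_annotation(cohort.records, outdir / "annotation.tsv")
    with open(outdir / "sequences.fasta", "w", encoding="utf-8") as fh:
        for r in cohort.records:
            fh.write(f">{r.accession}\n")
            for k in range(0, len(r.sequence), 60):
                fh.write(r.sequence[k : k + 60] + "\n")
    if config.with_structures:
        sdir = outdir / "structures"
        sdir.mkdir(exist_ok=True)
        for acc, st in cohort.structures.items():
            _write_structure_pdb(st, cohort.ligands[acc], sdir / f"{acc}.pdb")
    cohort.truth.to_json(outdir / "truth.json")
    return cohort.truth


# ---------------------------------------------------------------------------
# benchmark configs and truth checking


def motif_benchmark_config(seed: int) -> CohortConfig:
    """Single-family cohort for planted-motif recovery: 8 training sites
    plus one held-out site carrying a single motif substitution."""
    return CohortConfig(
        n_enzymes=9,
        n_families=1,
        n_family_pocket=0,
        class_mix={"I": 1.0},
        coupling_defect_rate=0.0,
        bridge_rate=0.0,
        seed=seed,
    )


def coupling_benchmark_config(seed: int, n_enzymes: int = 50) -> CohortConfig:
    """Cohort for sequence-product coupling recovery (no structures)."""
    return CohortConfig(n_enzymes=n_enzymes, with_structures=False, seed=seed)


def truth_check(
    truth: CohortTruth,
    class_labels: dict[str, ClassLabel] | None = None,
    motif_reference_keys: Sequence[tuple[str, int, str]] | None = None,
    motif_reference_id: str | None = None,
    correlation_r: float | None = None,
) -> dict:
    """Compare pipeline outputs against the planted ground truth.

    Reports class-label agreement, motif-position recovery, and the
    coupling-correlation error, for whichever outputs are supplied.
    """
    if class_labels is None and motif_reference_keys is None and correlation_r is None:
        raise ValueError("truth_check: no analysis outputs supplied")
    report: dict = {}
    if class_labels is not None:
        total = agree = 0
        for acc, planted in truth.class_labels.items():
            if acc in class_labels:
                total += 1
                agree += class_labels[acc] is ClassLabel.parse(planted)
        if total == 0:
            raise ValueError("truth_check: class label stage produced no output")
        report["class_agreement"] = agree / total
    if motif_reference_keys is not None:
        if motif_reference_id is None or motif_reference_id not in truth.pocket_positions:
            raise ValueError("truth_check: motif stage output lacks a known reference id")
        planted = set(truth.pocket_positions[motif_reference_id])
        found = {num for (_ch, num, _nm) in motif_reference_keys}
        report["motif_exact_recovery"] = found == planted
        report["motif_positions_found"] = sorted(found)
        report["motif_positions_planted"] = sorted(planted)
    if correlation_r is not None:
        report["coupling_r"] = correlation_r
        report["coupling_error"] = abs(correlation_r - truth.target_rho)
    return report
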
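"""Data model and file I/O for the curated diterpene-synthase dataset.

The pipeline revolves around a curated table of functionally characterized
plant diterpene synthases (one row per enzyme: accession, taxonomy, mechanistic
class, sequence, substrate, product SMILES, skeleton labels), protein sequences
in FASTA, and 3D structures with a bound ligand pose in PDB format.  This
module defines the in-memory types (:class:`EnzymeRecord`,
:class:`StructureModel`, :class:`LigandPose`, :class:`ResidueShell`) and the
readers/writers for every external format the pipeline touches.

The annotation table is a single TSV dialect defined here (documented in
:data:`ANNOTATION_COLUMNS`); a ``column_map`` argument adapts other layouts.
Residue numbers follow the PDB file; domain ranges are 1-based inclusive on
the sequence, matching the conventions biologists use for motif positions.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.SeqUtils import seq1

__all__ = [
    "ClassLabel",
    "ProductRef",
    "EnzymeRecord",
    "Atom",
    "Residue",
    "StructureModel",
    "LigandPose",
    "ResidueShell",
    "AnnotationResult",
    "AnnotationError",
    "read_annotation",
    "write_annotation",
    "read_fasta",
    "read_structure",
    "write_shell_pdb",
    "summarize_dataset",
]

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
#: Canonical annotation TSV header.  ``products`` holds ``;``-separated SMILES
#: (optionally ``name=SMILES``); ``skeletons`` holds ``;``-separated labels,
#: either one per product or a single label applied to all.
ANNOTATION_COLUMNS = (
    "accession",
    "species",
    "family",
    "genus",
    "class",
    "sequence",
    "domain_N",
    "domain_C",
    "substrate",
    "products",
    "skeletons",
)
REQUIRED_COLUMNS = ("accession", "class", "sequence", "substrate", "products", "skeletons")


class AnnotationError(ValueError):
    """Hard failure while reading the curated annotation table."""


class ClassLabel(enum.Enum):
    """Mechanistic class of a diterpene synthase.

    Class I enzymes initiate catalysis by ionization of the diphosphate
    (DDXXD / NSE-DTE motifs, alpha domain); class II by protonation-induced
    cyclization (DXDD motif, beta-gamma interface); bifunctional enzymes
    carry both active sites.
    """

    I = "I"
    II = "II"
    I_II = "I/II"
    UNKNOWN = "unknown"

    @classmethod
    def parse(cls, text: str) -> "ClassLabel":
        t = str(text).strip().upper().replace("-", "/").replace("_", "/")
        if t in {"I", "1"}:
            return cls.I
        if t in {"II", "2"}:
            return cls.II
        if t in {"I/II", "1/2", "II/I"}:
            return cls.I_II
        return cls.UNKNOWN


@dataclass(frozen=True)
class ProductRef:
    """One enzymatic product: a name, its SMILES, and a skeleton label."""

    name: str
    smiles: str
    skeleton: str = "unassigned"
    parseable: bool = True


@dataclass
class EnzymeRecord:
    """One curated enzyme: sequence, class, domains, substrate, products."""

    accession: str
    sequence: str
    class_label: ClassLabel = ClassLabel.UNKNOWN
    species: str = ""
    lineage: tuple[str, str] = ("", "")  # (family, genus)
    domain_ranges: dict[str, tuple[int, int]] | None = None
    substrate: str = ""
    products: list[ProductRef] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - STANDARD_AA - {"X"}
        if bad:
            raise ValueError(f"{self.accession}: non-standard letters {sorted(bad)}")
        if self.domain_ranges:
            n = len(self.sequence)
            for dom, (a, b) in self.domain_ranges.items():
                if not (1 <= a <= b <= n):
                    raise ValueError(
                        f"{self.accession}: domain {dom} range [{a},{b}] outside [1,{n}]"
                    )

    @property
    def skeleton_labels(self) -> list[str]:
        seen: list[str] = []
        for p in self.products:
            if p.skeleton not in seen:
                seen.append(p.skeleton)
        return seen or ["unassigned"]


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    xyz: tuple[float, float, float]


@dataclass(frozen=True)
class Residue:
    chain: str
    number: int
    name: str  # 3-letter
    atoms: tuple[Atom, ...]

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.number, self.name)

    @property
    def letter(self) -> str:
        code = seq1(self.name.capitalize())
        return code.upper() if code.upper() in STANDARD_AA else "X"

    @property
    def ca(self) -> np.ndarray | None:
        for a in self.atoms:
            if a.name == "CA":
                return np.asarray(a.xyz, dtype=float)
        return None

    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms], dtype=float)


@dataclass
class StructureModel:
    """Protein coordinates: an ordered list of residues with heavy atoms."""

    structure_id: str
    residues: list[Residue]

    def __post_init__(self) -> None:
        for r in self.residues:
            if not r.atoms:
                raise ValueError(f"{self.structure_id}: residue {r.key} has no atoms")
            if not np.isfinite(np.array([a.xyz for a in r.atoms])).all():
                raise ValueError(f"{self.structure_id}: non-finite coordinates in {r.key}")
        self.residues = sorted(self.residues, key=lambda r: (r.chain, r.number))

    def __len__(self) -> int:
        return len(self.residues)

    def ca_coords(self) -> np.ndarray:
        cas = [r.ca for r in self.residues if r.ca is not None]
        return np.array(cas, dtype=float)

    def sequence(self) -> str:
        return "".join(r.letter for r in self.residues)


@dataclass
class LigandPose:
    """A bound / docked small-molecule pose (heavy atoms only)."""

    ligand_id: str
    atoms: list[Atom]

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"{self.ligand_id}: ligand pose has no atoms")
        if not np.isfinite(self.coords()).all():
            raise ValueError(f"{self.ligand_id}: non-finite ligand coordinates")

    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms], dtype=float)


@dataclass
class ResidueShell:
    """Whole residues with any heavy atom within ``radius_A`` of the ligand.

    Mirrors the PyMOL selection ``byres all within r of ligand``: membership
    is decided atom-by-atom but whole residues are retained, in parent chain
    order.
    """

    structure_id: str
    radius_A: float
    residues: list[Residue]

    @property
    def residue_keys(self) -> list[tuple[str, int, str]]:
        return [r.key for r in self.residues]

    @property
    def shell_sequence(self) -> str:
        return "".join(r.letter for r in self.residues)

    def ca_coords(self) -> np.ndarray:
        return np.array([r.ca for r in self.residues if r.ca is not None], dtype=float)

    def __len__(self) -> int:
        return len(self.residues)


# ---------------------------------------------------------------------------
# annotation TSV


@dataclass
class AnnotationResult(Sequence):
    """Records parsed from an annotation table plus row-level warnings.

    Behaves as a sequence of :class:`EnzymeRecord`; ``warnings`` lists
    human-readable messages for malformed rows/products that were salvaged
    or dropped.
    """

    records: list[EnzymeRecord]
    warnings: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def __iter__(self) -> Iterator[EnzymeRecord]:
        return iter(self.records)


def _parse_range(cell: str) -> tuple[int, int] | None:
    cell = str(cell).strip()
    if not cell or cell.lower() in {"nan", "na", "-", ""}:
        return None
    a, b = cell.replace("..", "-").split("-")
    return int(a), int(b)


def _smiles_ok(smiles: str) -> bool:
    from rdkit import Chem
    from rdkit import RDLogger

    RDLogger.DisableLog("rdApp.error")
    return Chem.MolFromSmiles(smiles) is not None


def _parse_products(cell: str, skel_cell: str, warn: list[str], acc: str) -> list[ProductRef]:
    tokens = [t.strip() for t in str(cell).split(";") if t.strip()]
    skels = [s.strip() for s in str(skel_cell).split(";") if s.strip()]
    if len(skels) == len(tokens):
        per_product = skels
    elif len(skels) == 1:
        per_product = skels * len(tokens)
    else:
        if skels:
            warn.append(f"{acc}: {len(skels)} skeleton labels for {len(tokens)} products")
        per_product = ["unassigned"] * len(tokens)
    out = []
    for tok, skel in zip(tokens, per_product):
        name, _, smi = tok.partition("=")
        if not smi:
            name, smi = tok, tok
        ok = _smiles_ok(smi)
        if not ok:
            warn.append(f"{acc}: unparseable SMILES {smi!r}")
        out.append(ProductRef(name=name, smiles=smi, skeleton=skel or "unassigned", parseable=ok))
    return out


def read_annotation(
    path: str | Path,
    sequences: Mapping[str, str] | None = None,
    column_map: Mapping[str, str] | None = None,
) -> AnnotationResult:
    """Read the curated annotation TSV.

    Parameters
    ----------
    path:
        TSV with a header row; required columns are
        ``accession, class, sequence, substrate, products, skeletons``.
    sequences:
        Optional accession->sequence mapping (e.g. from :func:`read_fasta`);
        used when the ``sequence`` cell is empty or is a FASTA key.
    column_map:
        Mapping from canonical column names to the file's column names, to
        adapt foreign layouts.

    Malformed rows are collected as warnings on the returned
    :class:`AnnotationResult`; valid rows are still returned.  A missing
    required column is a hard :class:`AnnotationError`.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise AnnotationError(f"annotation table missing required column {col!r}")
    records: list[EnzymeRecord] = []
    warns: list[str] = []
    for idx, row in df.iterrows():
        acc = str(row["accession"]).strip()
        try:
            seq = str(row["sequence"]).strip().upper()
            if sequences is not None and (not seq or seq in sequences):
                seq = sequences.get(seq or acc, seq)
            ranges = {}
            for dom in ("N", "C"):
                col = f"domain_{dom}"
                if col in df.columns:
                    rng = _parse_range(row[col])
                    if rng:
                        ranges[dom] = rng
            products = _parse_products(row["products"], row.get("skeletons", ""), warns, acc)
            rec = EnzymeRecord(
                accession=acc,
                sequence=seq,
                class_label=ClassLabel.parse(row["class"]),
                species=str(row.get("species", "")).strip(),
                lineage=(str(row.get("family", "")).strip(), str(row.get("genus", "")).strip()),
                domain_ranges=ranges or None,
                substrate=str(row["substrate"]).strip(),
                products=products,
            )
        except (ValueError, KeyError) as exc:
            warns.append(f"row {idx} ({acc or '?'}): {exc}")
            continue
        records.append(rec)
    return AnnotationResult(records=records, warnings=warns)


def write_annotation(records: Iterable[EnzymeRecord], path: str | Path) -> None:
    """Write records back to the canonical annotation TSV layout."""
    rows = []
    for r in records:
        ranges = r.domain_ranges or {}
        rows.append(
            {
                "accession": r.accession,
                "species": r.species,
                "family": r.lineage[0],
                "genus": r.lineage[1],
                "class": r.class_label.value,
                "sequence": r.sequence,
                "domain_N": "-".join(map(str, ranges["N"])) if "N" in ranges else "",
                "domain_C": "-".join(map(str, ranges["C"])) if "C" in ranges else "",
                "substrate": r.substrate,
                "products": ";".join(f"{p.name}={p.smiles}" for p in r.products),
                "skeletons": ";".join(p.skeleton for p in r.products),
            }
        )
    pd.DataFrame(rows, columns=list(ANNOTATION_COLUMNS)).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an accession -> uppercased sequence mapping.

    The key is the header token before the first whitespace.  Duplicate keys
    are a hard failure (the curated set is keyed by unique accessions).
    """
    out: dict[str, str] = {}
    dupes: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in out:
                dupes.append(rec.id)
            out[rec.id] = str(rec.seq).upper()
    if dupes:
        raise ValueError(f"duplicate FASTA keys: {sorted(set(dupes))}")
    return out


# ---------------------------------------------------------------------------
# PDB


def _is_hydrogen(el: str, name: str) -> bool:
    e = el.strip().upper()
    if e in {"H", "D"}:
        return True
    return not e and name.strip().upper().lstrip("0123456789").startswith("H")


def read_structure(
    path: str | Path,
    ligand_codes: Iterable[str] = (),
    structure_id: str | None = None,
) -> tuple[StructureModel, LigandPose | None]:
    """Read a single-model PDB file into a structure and an optional ligand pose.

    ATOM records become the :class:`StructureModel`; HETATM residues whose
    name is in ``ligand_codes`` are pooled into a :class:`LigandPose`.  Waters
    (HOH/WAT) are ignored and hydrogens dropped everywhere.  Nonstandard
    ATOM residues are retained (their 1-letter code maps to X).
    """
    ligand_codes = {c.strip().upper() for c in ligand_codes}
    st = gemmi.read_pdb(str(path))
    sid = structure_id or Path(path).stem
    residues: list[Residue] = []
    lig_atoms: list[Atom] = []
    lig_names: list[str] = []
    model = st[0]
    for chain in model:
        for res in chain:
            resname = res.name.strip().upper()
            if resname in {"HOH", "WAT"}:
                continue
            atoms = tuple(
                Atom(a.name.strip(), (a.element.name or "").upper(), (a.pos.x, a.pos.y, a.pos.z))
                for a in res
                if not _is_hydrogen(a.element.name or "", a.name)
            )
            if not atoms:
                continue
            if res.het_flag == "H":
                if resname in ligand_codes:
                    lig_atoms.extend(atoms)
                    lig_names.append(resname)
                continue
            residues.append(Residue(chain.name, res.seqid.num, resname, atoms))
    if not residues:
        raise ValueError(f"{path}: no ATOM records")
    pose: LigandPose | None = None
    if lig_atoms:
        pose = LigandPose(ligand_id="+".join(sorted(set(lig_names))), atoms=lig_atoms)
    elif ligand_codes:
        warnings.warn(f"{path}: ligand codes {sorted(ligand_codes)} not found; empty pose")
    return StructureModel(structure_id=sid, residues=residues), pose


def write_shell_pdb(shell: ResidueShell, path: str | Path) -> None:
    """Write a residue shell as a PDB file, preserving chain order and numbering.

    Reading the file back with :func:`read_structure` reproduces the residue
    names, numbers, and coordinates to PDB precision (1e-3 A).
    """
    if not shell.residues:
        raise ValueError("refusing to write an empty shell")
    st = gemmi.Structure()
    st.name = shell.structure_id
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for res in shell.residues:
        if res.chain not in chains:
            chains[res.chain] = gemmi.Chain(res.chain)
        g = gemmi.Residue()
        g.name = res.name
        g.seqid = gemmi.SeqId(res.number, " ")
        for a in res.atoms:
            ga = gemmi.Atom()
            ga.name = a.name
            ga.element = gemmi.Element(a.element)
            ga.pos = gemmi.Position(*a.xyz)
            ga.occ = 1.0
            g.add_atom(ga)
        chains[res.chain].add_residue(g)
    for ch in chains.values():
        model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    doc = st.make_pdb_string()
    Path(path).write_text(doc, encoding="utf-8")


# ---------------------------------------------------------------------------
# dataset summary


def summarize_dataset(records: Iterable[EnzymeRecord]) -> dict[str, int]:
    """Headline counts for a curated dataset.

    Returns the number of records, the class partition, distinct species,
    distinct class II products (diterpene intermediates, phosphate retained),
    distinct class I / I-II products (diterpene precursors), and the number
    of skeleton types spanned by class I / I-II products.
    """
    records = list(records)
    by_class = {c: 0 for c in (ClassLabel.I, ClassLabel.II, ClassLabel.I_II, ClassLabel.UNKNOWN)}
    species, intermediates, precursors, skeletons = set(), set(), set(), set()
    for r in records:
        by_class[r.class_label] += 1
        if r.species:
            species.add(r.species)
        names = {p.name for p in r.products}
        if r.class_label is ClassLabel.II:
            intermediates |= names
        elif r.class_label in (ClassLabel.I, ClassLabel.I_II):
            precursors |= names
            skeletons |= {p.skeleton for p in r.products}
    return {
        "n_records": len(records),
        "n_class_I": by_class[ClassLabel.I],
        "n_class_II": by_class[ClassLabel.II],
        "n_class_I_II": by_class[ClassLabel.I_II],
        "n_class_unknown": by_class[ClassLabel.UNKNOWN],
        "n_species": len(species),
        "n_intermediates": len(intermediates),
        "n_precursors": len(precursors),
        "n_skeleton_types_I": len(skeletons),
    }
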
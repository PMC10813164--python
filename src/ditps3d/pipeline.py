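"""End-to-end orchestration of the sequence-structure-product analysis.

Stages run in dependency order on any compliant input directory (curated
annotation TSV, FASTA, PDB structures with a bound ligand):

    curate -> seqsim -> ssn -> shells -> structsim -> motifs ->
    motif_search -> chemsim -> stats -> report

Each stage writes its outputs under the configured output directory and is
skipped on rerun when its outputs already exist (delete a stage's outputs
to regenerate it and everything that reads them).  Every run echoes the
full parameter set to ``config.yaml`` and appends structured lines to
``logs/pipeline.log`` so row-level exclusions (unparseable products, small
shells) stay traceable.
"""

from __future__ import annotations

import dataclasses
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io_model, seq_analysis, struct_align, motif3d, chem_products, stats_corr
from .io_model import ClassLabel

__all__ = ["PipelineConfig", "run_pipeline", "summarize", "STAGES"]


@dataclass
class PipelineConfig:
    """All figure-level knobs of the analysis, auditable in one place."""

    annotation: str
    outdir: str
    fasta: str | None = None
    structures_dir: str | None = None
    ligand_codes: list[str] = field(default_factory=lambda: ["GGP"])
    radii: list[float] = field(default_factory=lambda: [4.0, 6.0, 8.0, 10.0])
    # shell radius used for motif extraction, per product group: 6 A for
    # diterpene-skeleton producers (class I and I/II), 8 A for
    # intermediate-producing class II enzymes
    motif_radius_skeleton: float = 6.0
    motif_radius_intermediate: float = 8.0
    ssn_thresholds: list[float] = field(default_factory=lambda: [40.0, 50.0, 60.0, 70.0])
    fingerprint_radius: int = 2
    fingerprint_bits: int = 2048
    benjamini_hochberg: bool = False
    query_structures: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        radii = [float(r) for r in self.radii]
        if any(r <= 0 for r in radii) or radii != sorted(radii):
            raise ValueError("shell radii must be positive and ascending")
        self.radii = radii

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=False), encoding="utf-8"
        )

    def validate_paths(self) -> None:
        if not Path(self.annotation).exists():
            raise FileNotFoundError(f"annotation table not found: {self.annotation}")
        for label, p in (
            ("fasta", self.fasta),
            ("structures_dir", self.structures_dir),
            ("query_structures", self.query_structures),
        ):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{label} not found: {p}")


class _Ctx:
    """Mutable state threaded through the stages of one run."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.outdir = Path(config.outdir)
        self.records: list[io_model.EnzymeRecord] = []
        self.structures: dict[str, io_model.StructureModel] = {}
        self.ligands: dict[str, io_model.LigandPose] = {}
        self.shells: dict[float, dict[str, io_model.ResidueShell]] = {}
        self.log_path = self.outdir / "logs" / "pipeline.log"

    def log(self, stage: str, message: str) -> None:
        self.log_path.parent.mkdir(parents=True, exist_ok=True)
        stamp = time.strftime("%Y-%m-%d %H:%M:%S")
        with open(self.log_path, "a", encoding="utf-8") as fh:
            fh.write(f"{stamp}\t{stage}\t{message}\n")


# ---------------------------------------------------------------------------
# stages


def _stage_curate(ctx: _Ctx) -> None:
    cfg = ctx.config
    sequences = io_model.read_fasta(cfg.fasta) if cfg.fasta else None
    result = io_model.read_annotation(cfg.annotation, sequences=sequences)
    ctx.records = result.records
    out = ctx.outdir / "curated"
    out.mkdir(parents=True, exist_ok=True)
    io_model.write_annotation(result.records, out / "annotation_curated.tsv")
    (out / "warnings.txt").write_text("\n".join(result.warnings), encoding="utf-8")
    summary = io_model.summarize_dataset(result.records)
    (out / "dataset_summary.json").write_text(json.dumps(summary, indent=2), encoding="utf-8")
    ctx.log("curate", f"records={len(result.records)} warnings={len(result.warnings)}")


def _load_records(ctx: _Ctx) -> None:
    if not ctx.records:
        path = ctx.outdir / "curated" / "annotation_curated.tsv"
        src = path if path.exists() else ctx.config.annotation
        sequences = io_model.read_fasta(ctx.config.fasta) if ctx.config.fasta else None
        ctx.records = io_model.read_annotation(src, sequences=sequences).records


def _stage_seqsim(ctx: _Ctx) -> None:
    _load_records(ctx)
    out = ctx.outdir / "seqsim"
    out.mkdir(parents=True, exist_ok=True)
    for region in ("N", "C", "NC", "full"):
        mat = seq_analysis.similarity_matrix(ctx.records, region)
        mat.to_tsv(out / f"seq_{region}.tsv")
        ctx.log("seqsim", f"region={region} n={len(mat.ids)}")


def _stage_ssn(ctx: _Ctx) -> None:
    _load_records(ctx)
    out = ctx.outdir / "ssn"
    out.mkdir(parents=True, exist_ok=True)
    mat = seq_analysis.SimilarityMatrix.from_tsv(
        ctx.outdir / "seqsim" / "seq_full.tsv", kind="seq_full", scale="percent"
    )
    attrs = {
        r.accession: {
            "class": r.class_label.value,
            "skeletons": ";".join(r.skeleton_labels),
        }
        for r in ctx.records
    }
    for thr in ctx.config.ssn_thresholds:
        g = seq_analysis.build_ssn(mat, thr, node_attrs=attrs)
        seq_analysis.write_ssn(
            g, out / f"ssn_full_t{int(thr)}.tsv", out / f"ssn_full_t{int(thr)}.graphml"
        )
        ctx.log("ssn", f"threshold={thr} nodes={g.number_of_nodes()} edges={g.number_of_edges()}")


def _read_structures(ctx: _Ctx) -> None:
    if ctx.structures:
        return
    cfg = ctx.config
    if not cfg.structures_dir:
        raise ValueError("structsim/shells stages need structures_dir")
    for pdb in sorted(Path(cfg.structures_dir).glob("*.pdb")):
        model, pose = io_model.read_structure(pdb, ligand_codes=cfg.ligand_codes)
        ctx.structures[model.structure_id] = model
        if pose is not None:
            ctx.ligands[model.structure_id] = pose


def _stage_shells(ctx: _Ctx) -> None:
    _read_structures(ctx)
    out = ctx.outdir / "shells"
    rows = []
    for radius in ctx.config.radii:
        rdir = out / f"r{int(radius)}"
        rdir.mkdir(parents=True, exist_ok=True)
        ctx.shells[radius] = {}
        for sid, model in ctx.structures.items():
            if sid not in ctx.ligands:
                ctx.log("shells", f"{sid}: no ligand pose; skipped")
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                shell = struct_align.extract_shell(model, ctx.ligands[sid], radius)
            ctx.shells[radius][sid] = shell
            if len(shell):
                io_model.write_shell_pdb(shell, rdir / f"{sid}.pdb")
            rows.append(
                {
                    "structure_id": sid,
                    "radius_A": radius,
                    "n_residues": len(shell),
                    "shell_sequence": shell.shell_sequence,
                }
            )
        ctx.log("shells", f"radius={radius} shells={len(ctx.shells[radius])}")
    pd.DataFrame(rows).to_csv(out / "shell_summary.tsv", sep="\t", index=False)


def _load_shells(ctx: _Ctx) -> None:
    if not ctx.shells:
        _stage_shells(ctx)


def _stage_structsim(ctx: _Ctx) -> None:
    _read_structures(ctx)
    _load_shells(ctx)
    out = ctx.outdir / "structsim"
    out.mkdir(parents=True, exist_ok=True)
    gmat = struct_align.global_tm_matrix(ctx.structures)
    gmat.to_tsv(out / "tm_global.tsv")
    ctx.log("structsim", f"global n={len(gmat.ids)}")
    for radius in ctx.config.radii:
        mat = struct_align.shell_tm_matrix(ctx.shells[radius], radius)
        mat.to_tsv(out / f"tm_shell_{int(radius)}.tsv")
        ctx.log("structsim", f"shell radius={radius} n={len(mat.ids)}")


def _motif_groups(ctx: _Ctx) -> dict[str, tuple[float, list[str]]]:
    """Product groups for motif extraction: (shell radius, member accessions)."""
    cfg = ctx.config
    skeleton = [
        r.accession
        for r in ctx.records
        if r.class_label in (ClassLabel.I, ClassLabel.I_II)
    ]
    intermediate = [
        r.accession for r in ctx.records if r.class_label is ClassLabel.II
    ]
    return {
        "skeleton": (cfg.motif_radius_skeleton, skeleton),
        "intermediate": (cfg.motif_radius_intermediate, intermediate),
    }


def _stage_motifs(ctx: _Ctx) -> None:
    _load_records(ctx)
    _read_structures(ctx)
    _load_shells(ctx)
    out = ctx.outdir / "motifs"
    out.mkdir(parents=True, exist_ok=True)
    for group, (radius, members) in _motif_groups(ctx).items():
        shells = [
            ctx.shells.get(radius, {}).get(acc)
            for acc in members
            if ctx.shells.get(radius, {}).get(acc) is not None
        ]
        shells = [s for s in shells if len(s) >= 4]
        if len(shells) < 2:
            ctx.log("motifs", f"group={group}: fewer than 2 usable shells; skipped")
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            aln = motif3d.align_sites(shells)
        profile = motif3d.conservation_profile(aln)
        profile.to_csv(out / f"conservation_{group}.tsv", sep="\t")
        logo = profile.drop(columns=["gap"]).reset_index().melt(
            id_vars="column", var_name="letter", value_name="frequency"
        )
        logo[logo["frequency"] > 0].to_csv(out / f"logo_{group}.tsv", sep="\t", index=False)
        try:
            motif = motif3d.extract_motif(aln)
        except ValueError as exc:
            ctx.log("motifs", f"group={group}: {exc}")
            continue
        motif.to_json(out / f"motif_{group}.json")
        ctx.log(
            "motifs",
            f"group={group} radius={radius} sites={len(shells)} positions={len(motif.positions)}",
        )


def _stage_motif_search(ctx: _Ctx) -> None:
    _read_structures(ctx)
    out = ctx.outdir / "motif_search"
    out.mkdir(parents=True, exist_ok=True)
    motif_dir = ctx.outdir / "motifs"
    cfg = ctx.config
    if cfg.query_structures:
        queries = {}
        for pdb in sorted(Path(cfg.query_structures).glob("*.pdb")):
            model, _ = io_model.read_structure(pdb, ligand_codes=cfg.ligand_codes)
            queries[model.structure_id] = model
    else:
        queries = ctx.structures
    for mjson in sorted(motif_dir.glob("motif_*.json")):
        motif = motif3d.Motif3D.from_json(mjson)
        group = mjson.stem.replace("motif_", "")
        all_matches = []
        for sid, query in queries.items():
            for policy in ("strict", "relaxed"):
                for m in motif3d.search_motif(motif, query, policy):
                    all_matches.append((policy, m))
        rows = []
        for policy, m in all_matches:
            rows.append(
                {
                    "policy": policy,
                    "structure_id": m.structure_id,
                    "residues": ";".join(f"{c}{n}:{r}" for c, n, r in m.residue_keys),
                    "rmsd_A": m.rmsd_A,
                    "mismatches": m.mismatches,
                }
            )
        pd.DataFrame(
            rows, columns=["policy", "structure_id", "residues", "rmsd_A", "mismatches"]
        ).to_csv(out / f"matches_{group}.tsv", sep="\t", index=False)
        ctx.log("motif_search", f"group={group} queries={len(queries)} matches={len(rows)}")


def _stage_chemsim(ctx: _Ctx) -> None:
    _load_records(ctx)
    out = ctx.outdir / "chemsim"
    out.mkdir(parents=True, exist_ok=True)
    cfg = ctx.config
    mat = chem_products.product_similarity_matrix(
        ctx.records, radius=cfg.fingerprint_radius, n_bits=cfg.fingerprint_bits
    )
    mat.to_tsv(out / "product_dsc.tsv")
    skeletons = []
    for r in ctx.records:
        for p in r.products:
            if p.parseable:
                skeletons.append(
                    {
                        "accession": r.accession,
                        "product": p.name,
                        "skeleton_label": p.skeleton,
                        "carbon_skeleton": chem_products.skeletonize(p.smiles),
                    }
                )
    pd.DataFrame(skeletons).to_csv(out / "skeletons.tsv", sep="\t", index=False)
    ctx.log("chemsim", f"n={len(mat.ids)}")


def _factor_matrices(ctx: _Ctx) -> dict[str, seq_analysis.SimilarityMatrix]:
    factors: dict[str, seq_analysis.SimilarityMatrix] = {}
    spec = [
        ("seq_N", ctx.outdir / "seqsim" / "seq_N.tsv", "percent"),
        ("seq_C", ctx.outdir / "seqsim" / "seq_C.tsv", "percent"),
        ("seq_NC", ctx.outdir / "seqsim" / "seq_NC.tsv", "percent"),
        ("seq_full", ctx.outdir / "seqsim" / "seq_full.tsv", "percent"),
        ("tm_global", ctx.outdir / "structsim" / "tm_global.tsv", "unit"),
        ("product_dsc", ctx.outdir / "chemsim" / "product_dsc.tsv", "unit"),
    ]
    for radius in ctx.config.radii:
        spec.append(
            (
                f"tm_shell_{int(radius)}",
                ctx.outdir / "structsim" / f"tm_shell_{int(radius)}.tsv",
                "unit",
            )
        )
    for kind, path, scale in spec:
        if path.exists():
            factors[kind] = seq_analysis.SimilarityMatrix.from_tsv(path, kind=kind, scale=scale)
    return factors


def _stage_stats(ctx: _Ctx) -> None:
    _load_records(ctx)
    out = ctx.outdir / "stats"
    out.mkdir(parents=True, exist_ok=True)
    # composition and preference tables (need shells)
    shell_summary = ctx.outdir / "shells" / "shell_summary.tsv"
    if shell_summary.exists():
        df = pd.read_csv(shell_summary, sep="\t").fillna({"shell_sequence": ""})
        seq_by_id = {}
        if ctx.config.structures_dir:
            _read_structures(ctx)
            seq_by_id = {sid: m.sequence() for sid, m in ctx.structures.items()}
        comp_rows, pref_rows = [], []
        for _, row in df.iterrows():
            sid = row["structure_id"]
            full = seq_by_id.get(sid, "")
            shell_letters = str(row["shell_sequence"] or "")
            comp = stats_corr.composition(shell_letters)
            comp_rows.append(
                {"structure_id": sid, "radius_A": row["radius_A"], **comp.aac, **comp.gaac}
            )
            if full and shell_letters:
                pref = stats_corr.preference(shell_letters, full)
                pref_rows.append(
                    {"structure_id": sid, "radius_A": row["radius_A"], **pref.ratio}
                )
        pd.DataFrame(comp_rows).to_csv(out / "composition_shells.tsv", sep="\t", index=False)
        pd.DataFrame(pref_rows).to_csv(out / "preference_shells.tsv", sep="\t", index=False)
    full_comp = [
        {"accession": r.accession, **stats_corr.composition(r.sequence).aac}
        for r in ctx.records
    ]
    pd.DataFrame(full_comp).to_csv(out / "composition_full.tsv", sep="\t", index=False)
    # correlations over all available factors
    factors = _factor_matrices(ctx)
    if len(factors) >= 2:
        report = stats_corr.correlation_report(
            factors, benjamini_hochberg=ctx.config.benjamini_hochberg
        )
        report.to_tsv(out / "correlations.tsv")
        ctx.log("stats", f"correlations factors={len(factors)}")
    # same-vs-different group comparisons
    rows = []
    for key in ("substrate", "product_skeleton"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            same, different = stats_corr.pair_partition(ctx.records, key)
        for kind, mat in factors.items():
            vs = stats_corr.pair_values(mat, same)
            vd = stats_corr.pair_values(mat, different)
            if len(vs) < 3 or len(vd) < 3:
                continue
            cmp = stats_corr.group_compare(vs, vd)
            rows.append(
                {
                    "key": key,
                    "factor": kind,
                    "U": cmp["U"],
                    "p": cmp["p"],
                    "method": cmp["method"],
                    "median_same": cmp["same"]["median"],
                    "median_different": cmp["different"]["median"],
                    "q1_same": cmp["same"]["q1"],
                    "q3_same": cmp["same"]["q3"],
                    "q1_different": cmp["different"]["q1"],
                    "q3_different": cmp["different"]["q3"],
                }
            )
    pd.DataFrame(rows).to_csv(out / "group_comparisons.tsv", sep="\t", index=False)
    ctx.log("stats", f"group comparisons rows={len(rows)}")


def _stage_report(ctx: _Ctx) -> None:
    text = summarize(ctx.outdir)
    (ctx.outdir / "report.txt").write_text(text, encoding="utf-8")
    ctx.log("report", "written")


#: stage name -> (function, outputs that mark the stage as done)
STAGES: dict[str, tuple[Callable[[_Ctx], None], list[str]]] = {
    "curate": (_stage_curate, ["curated/annotation_curated.tsv"]),
    "seqsim": (_stage_seqsim, ["seqsim/seq_full.tsv"]),
    "ssn": (_stage_ssn, ["ssn"]),
    "shells": (_stage_shells, ["shells/shell_summary.tsv"]),
    "structsim": (_stage_structsim, ["structsim/tm_global.tsv"]),
    "motifs": (_stage_motifs, ["motifs"]),
    "motif_search": (_stage_motif_search, ["motif_search"]),
    "chemsim": (_stage_chemsim, ["chemsim/product_dsc.tsv"]),
    "stats": (_stage_stats, ["stats/group_comparisons.tsv"]),
    "report": (_stage_report, ["report.txt"]),
}

_STRUCTURE_STAGES = {"shells", "structsim", "motifs", "motif_search"}


def run_pipeline(
    config: PipelineConfig,
    stages: Sequence[str] | None = None,
    force: bool = False,
) -> Path:
    """Run the analysis stages in dependency order; returns the output dir.

    Stages whose outputs already exist are skipped unless ``force``.  A
    stage failure raises after logging; outputs of earlier stages are
    preserved.
    """
    config.validate_paths()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    ctx = _Ctx(config)
    selected = list(STAGES) if stages is None else list(stages)
    unknown = [s for s in selected if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stages: {unknown}")
    for name in STAGES:
        if name not in selected:
            continue
        if name in _STRUCTURE_STAGES and not config.structures_dir:
            ctx.log(name, "skipped: no structures_dir configured")
            continue
        fn, markers = STAGES[name]
        if not force and markers and all((outdir / m).exists() for m in markers):
            ctx.log(name, "skipped: outputs present")
            continue
        t0 = time.time()
        try:
            fn(ctx)
        except Exception as exc:
            ctx.log(name, f"FAILED: {exc}")
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        ctx.log(name, f"done in {time.time() - t0:.1f}s")
    return outdir


# ---------------------------------------------------------------------------
# report


def _quartile_block(path: Path, label: str) -> list[str]:
    mat = pd.read_csv(path, sep="\t", index_col=0)
    vals = mat.values[np.triu_indices(len(mat), k=1)]
    vals = vals[~np.isnan(vals)]
    if not len(vals):
        return [f"{label}: no data"]
    q1, med, q3 = np.percentile(vals, [25, 50, 75])
    return [f"{label}: n_pairs={len(vals)} Q1={q1:.3g} median={med:.3g} Q3={q3:.3g}"]


def summarize(output_dir: str | Path) -> str:
    """Human-readable report over a completed (or partial) run."""
    outdir = Path(output_dir)
    lines: list[str] = ["# Analysis summary", ""]
    lines.append("## Pairwise similarity distributions")
    any_factor = False
    for name, label in [
        ("seqsim/seq_N.tsv", "N-terminal identity (%)"),
        ("seqsim/seq_C.tsv", "C-terminal identity (%)"),
        ("seqsim/seq_NC.tsv", "NC identity (%)"),
        ("seqsim/seq_full.tsv", "full-sequence identity (%)"),
        ("structsim/tm_global.tsv", "global TM-score"),
        ("structsim/tm_shell_4.tsv", "shell TM-score (4 A)"),
        ("structsim/tm_shell_6.tsv", "shell TM-score (6 A)"),
        ("structsim/tm_shell_8.tsv", "shell TM-score (8 A)"),
        ("structsim/tm_shell_10.tsv", "shell TM-score (10 A)"),
        ("chemsim/product_dsc.tsv", "product Dice"),
    ]:
        p = outdir / name
        if p.exists():
            lines += _quartile_block(p, label)
            any_factor = True
    if not any_factor:
        lines.append("(not run)")
    lines.append("")
    lines.append("## Factor correlations (Pearson)")
    corr = outdir / "stats" / "correlations.tsv"
    if corr.exists():
        df = pd.read_csv(corr, sep="\t")
        for _, row in df.iterrows():
            lines.append(
                f"{row['factor_a']} vs {row['factor_b']}: r={row['r']:.3f} "
                f"p={row['p']:.2g} n={int(row['n'])}"
            )
    else:
        lines.append("(not run)")
    lines.append("")
    lines.append("## Same vs different comparisons (Mann-Whitney U)")
    gc = outdir / "stats" / "group_comparisons.tsv"
    if gc.exists():
        df = pd.read_csv(gc, sep="\t")
        for _, row in df.iterrows():
            lines.append(
                f"{row['key']} / {row['factor']}: U={row['U']:.0f} p={row['p']:.2g} "
                f"median same={row['median_same']:.3g} different={row['median_different']:.3g}"
            )
    else:
        lines.append("(not run)")
    lines.append("")
    lines.append("## 3D motif inventory")
    motif_dir = outdir / "motifs"
    motifs = sorted(motif_dir.glob("motif_*.json")) if motif_dir.exists() else []
    if motifs:
        for mjson in motifs:
            data = json.loads(mjson.read_text(encoding="utf-8"))
            consensus = "".join(p["consensus"] for p in data["positions"])
            lines.append(
                f"{mjson.stem}: {len(data['positions'])} positions "
                f"consensus={consensus} support={data['support']} sites"
            )
    else:
        lines.append("(not run)")
    lines.append("")
    return "\n".join(lines)
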
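"""End-to-end pipeline orchestration.

Runs the stages in dependency order — simulate -> proteome DE -> codon bias;
counts -> p/RTS ranking; connectomes -> NBS; peak areas -> normalization —
communicating only through the documented on-disk formats, and writes a run
manifest (config hash, derived seeds, per-stage parameters, outputs and
wall time).  All randomness flows from one master seed via fixed per-stage
derived seeds, so re-running a config reproduces identical result files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import codon, nbs, proteome, synthetic, transcript, trna
from .config import SimConfig

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"

_SCHEMA = {
    "seed": int,
    "simulate": dict,
    "proteome": {"trim": float, "fdr": float},
    "rank": {"top_n": int, "cpm_cutoff": float, "min_samples": int,
             "literal_filter": bool},
    "nbs": {"n_perm": int, "directions": list, "t_range": list},
    "trna": {"n_perm": int, "control": str},
}

_DEFAULTS = {
    "seed": 0,
    "simulate": {},
    "proteome": {"trim": 0.2, "fdr": 0.1},
    "rank": {"top_n": 50, "cpm_cutoff": 0.5, "min_samples": 6,
             "literal_filter": False},
    "nbs": {"n_perm": 1000, "directions": ["increase", "decrease"],
            "t_range": [round(2.5 + 0.1 * i, 1) for i in range(11)]},
    "trna": {"n_perm": 2000, "control": "control"},
}

# derived-seed offsets per randomized stage
_STAGE_SEED = {"nbs": 101, "trna": 102}


class PipelineConfigError(ValueError):
    pass


def validate_config(config: dict) -> dict:
    """Merge with defaults; reject unknown keys, listing every offender."""
    bad = []
    for key in config:
        if key not in _SCHEMA:
            bad.append(key)
        elif isinstance(_SCHEMA[key], dict) and isinstance(config[key], dict):
            bad.extend(f"{key}.{sub}" for sub in config[key]
                       if sub not in _SCHEMA[key])
    if bad:
        raise PipelineConfigError(f"unknown config keys: {sorted(bad)}")
    merged = {}
    for key, default in _DEFAULTS.items():
        if isinstance(default, dict):
            merged[key] = {**default, **config.get(key, {})}
        else:
            merged[key] = config.get(key, default)
    return merged


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)


def _derived_seed(master: int, stage: str) -> int:
    return int(np.random.default_rng([int(master),
                                      _STAGE_SEED[stage]]).integers(2 ** 31))


# ---------------------------------------------------------------------------
# stages


def stage_simulate(config: SimConfig, outdir: Path) -> dict[str, str]:
    outdir.mkdir(parents=True, exist_ok=True)
    records, cds_truth = synthetic.simulate_cds(config)
    synthetic.write_fasta(records, outdir / "cds.fasta")
    _write_tsv(cds_truth, outdir / "cds_truth.tsv")

    peptides, prot_truth = synthetic.simulate_proteome(config, cds_truth)
    _write_tsv(peptides.to_table(), outdir / "peptides.tsv")
    _write_tsv(peptides.design.reset_index(), outdir / "peptide_design.tsv")
    _write_tsv(prot_truth, outdir / "protein_truth.tsv")

    counts, design, rts, gene_truth = synthetic.simulate_counts_rts(config)
    _write_tsv(counts.reset_index(), outdir / "counts.tsv")
    _write_tsv(design.reset_index(), outdir / "count_design.tsv")
    _write_tsv(rts, outdir / "rts.tsv")
    _write_tsv(gene_truth, outdir / "gene_truth.tsv")

    mats, groups, nodes, planted = synthetic.simulate_connectomes(config)
    conn_dir = outdir / "connectomes"
    conn_dir.mkdir(exist_ok=True)
    for subj, mat in mats.items():
        np.savetxt(conn_dir / f"{subj}.txt", mat, fmt="%d")
    (outdir / "node_labels.txt").write_text("\n".join(nodes) + "\n")
    _write_tsv(groups, outdir / "connectome_groups.tsv")
    _write_tsv(pd.DataFrame(planted, columns=["node_a", "node_b"]),
               outdir / "planted_edges.tsv")

    areas, mod_truth = synthetic.simulate_modifications(config)
    _write_tsv(areas, outdir / "modification_areas.tsv")
    with open(outdir / "modification_truth.json", "w") as fh:
        json.dump(mod_truth, fh, indent=2, sort_keys=True)

    return {p.name: str(p) for p in sorted(outdir.glob("*"))}


def stage_proteome(peptides_tsv: Path, design_tsv: Path, outdir: Path,
                   trim: float = 0.2, fdr: float = 0.1) -> dict[str, str]:
    outdir.mkdir(parents=True, exist_ok=True)
    matrix = proteome.PeptideMatrix.from_tables(
        pd.read_csv(peptides_tsv, sep="\t"),
        pd.read_csv(design_tsv, sep="\t"))
    normalized, diag = proteome.normalize_peptides(matrix)
    sigma2_tech = proteome.estimate_technical_variance(normalized)
    fit = proteome.fit_moderated_model(normalized, sigma2_tech)
    de = proteome.rollup_proteins(fit, trim=trim, fdr_threshold=fdr)
    _write_tsv(de.table.reset_index(), outdir / "protein_de.tsv")
    _write_tsv(fit.table.reset_index(), outdir / "peptide_stats.tsv")
    _write_tsv(diag, outdir / "loess_diagnostics.tsv")
    meta = {"sigma2_tech": fit.sigma2_tech, "s0_squared": fit.s0_squared,
            "d0": fit.d0 if np.isfinite(fit.d0) else "inf",
            "trim": trim, "fdr": fdr}
    with open(outdir / "proteome_meta.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
    return {"protein_de": str(outdir / "protein_de.tsv"),
            "peptide_stats": str(outdir / "peptide_stats.tsv"),
            "meta": str(outdir / "proteome_meta.json")}


def stage_codon(cds_fasta: Path, protein_de_tsv: Path,
                outdir: Path) -> dict[str, str]:
    outdir.mkdir(parents=True, exist_ok=True)
    de = pd.read_csv(protein_de_tsv, sep="\t").set_index("protein_id")
    up_ids = set(de.index[de["call"] == "up"])
    down_ids = set(de.index[de["call"] == "down"])
    seqs = dict(synthetic.read_fasta(cds_fasta))
    profiles = {g: codon.rscu_profile(s, g) for g, s in seqs.items()}
    up = [profiles[g] for g in sorted(up_ids) if g in profiles]
    down = [profiles[g] for g in sorted(down_ids) if g in profiles]
    n_unmapped = (len(up_ids) - len(up)) + (len(down_ids) - len(down))
    if n_unmapped:
        logger.warning("%d DE proteins had no CDS and were dropped",
                       n_unmapped)

    result = codon.compare_codon_usage(up, down)
    _write_tsv(result.per_codon.reset_index(), outdir / "codon_bias.tsv")
    cls = codon.codon_class_enrichment(up, down)
    _write_tsv(pd.DataFrame([cls]), outdir / "codon_class.tsv")

    lengths = {g: len(seqs[g]) // 3 - 1 for g in profiles}  # aa incl. Met
    reference = np.array([lengths[g] for g in sorted(de.index)
                          if g in lengths])
    rows = []
    for label, ids in (("up", up_ids), ("down", down_ids)):
        set_lengths = np.array([lengths[g] for g in sorted(ids)
                                if g in lengths])
        if set_lengths.size < 2:
            rows.append({"set": label, "n": int(set_lengths.size),
                         "degenerate": True})
            continue
        res = codon.length_bias_test(set_lengths, reference)
        rows.append({"set": label, "n": int(set_lengths.size), **res})
    _write_tsv(pd.DataFrame(rows), outdir / "length_bias.tsv")
    return {"codon_bias": str(outdir / "codon_bias.tsv"),
            "codon_class": str(outdir / "codon_class.tsv"),
            "length_bias": str(outdir / "length_bias.tsv")}


def stage_rank(counts_tsv: Path, design_tsv: Path, rts_tsv: Path,
               outdir: Path, top_n: int = 50, cpm_cutoff: float = 0.5,
               min_samples: int = 6,
               literal_filter: bool = False) -> dict[str, str]:
    outdir.mkdir(parents=True, exist_ok=True)
    counts = pd.read_csv(counts_tsv, sep="\t").set_index("gene_id")
    design = pd.read_csv(design_tsv, sep="\t").set_index("sample")
    rts = pd.read_csv(rts_tsv, sep="\t").set_index("gene_id")["rts"]
    cm = transcript.CountMatrix(counts=counts, design=design)
    cm, report = transcript.filter_counts(cm, cpm_cutoff=cpm_cutoff,
                                          min_samples=min_samples,
                                          literal=literal_filter)
    logger.info("count filter: kept %d, removed %d genes",
                report["kept"], report["removed"])
    factors = transcript.tmm_normalize(cm)
    de = transcript.gene_de_test(cm, norm_factors=factors)
    ranked = transcript.triage_rerank(de["p"], np.sign(de["log2fc"]),
                                      rts, top_n=top_n)
    _write_tsv(de.reset_index(), outdir / "gene_de.tsv")
    _write_tsv(ranked.table.reset_index(), outdir / "ranked_genes.tsv")
    _write_tsv(ranked.top.reset_index(), outdir / f"top_{top_n}_genes.tsv")
    _write_tsv(factors.reset_index(), outdir / "tmm_factors.tsv")
    return {"gene_de": str(outdir / "gene_de.tsv"),
            "ranked_genes": str(outdir / "ranked_genes.tsv"),
            "top_genes": str(outdir / f"top_{top_n}_genes.tsv")}


def load_connectomes(matrix_dir: Path, groups_tsv: Path,
                     node_labels: Path | None = None) -> nbs.ConnectomeSet:
    groups = pd.read_csv(groups_tsv, sep="\t").set_index("subject")["group"]
    matrices = {}
    for subj in groups.index:
        path = Path(matrix_dir) / f"{subj}.txt"
        if not path.exists():
            raise FileNotFoundError(f"missing connectome matrix: {path}")
        mat = np.loadtxt(path)
        # tolerate tiny asymmetries from on-disk rounding
        if not np.array_equal(mat, mat.T) and np.allclose(mat, mat.T,
                                                          atol=1e-6):
            mat = (mat + mat.T) / 2.0
        matrices[subj] = mat
    labels = []
    if node_labels is not None and Path(node_labels).exists():
        labels = Path(node_labels).read_text().split()
    return nbs.ConnectomeSet(matrices=matrices, groups=groups,
                             node_labels=labels)


def stage_nbs(matrix_dir: Path, groups_tsv: Path, outdir: Path,
              n_perm: int = 1000, seed: int | None = None,
              directions: tuple[str, ...] = ("increase", "decrease"),
              t_range: tuple[float, ...] | None = None,
              node_labels: Path | None = None) -> dict[str, str]:
    outdir.mkdir(parents=True, exist_ok=True)
    conn = load_connectomes(matrix_dir, groups_tsv, node_labels)
    outputs = {}
    for direction in directions:
        results, best = nbs.scan_thresholds(conn, direction=direction,
                                            t_range=t_range, n_perm=n_perm,
                                            seed=seed)
        payload = {
            "direction": direction,
            "seed": seed,
            "best_threshold": best.t_primary,
            "best_fwer_p": best.min_fwer_p,
            "thresholds": [
                {"t_primary": r.t_primary,
                 "min_fwer_p": r.min_fwer_p,
                 "n_perm": r.n_perm,
                 "components": [{"extent": c.extent, "fwer_p": c.fwer_p}
                                for c in r.components]}
                for r in results
            ],
        }
        path = outdir / f"nbs_{direction}.json"
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
        outputs[f"nbs_{direction}"] = str(path)
        largest = best.largest
        edges = pd.DataFrame(largest.edges if largest else [],
                             columns=["node_a", "node_b"])
        if conn.node_labels:
            edges["label_a"] = [conn.node_labels[a] for a in edges["node_a"]]
            edges["label_b"] = [conn.node_labels[b] for b in edges["node_b"]]
        epath = outdir / f"nbs_{direction}_component_edges.tsv"
        _write_tsv(edges, epath)
        outputs[f"nbs_{direction}_edges"] = str(epath)
    return outputs


def stage_trna(areas_tsv: Path, outdir: Path, control: str = "control",
               n_perm: int = 2000, seed: int | None = None) -> dict[str, str]:
    outdir.mkdir(parents=True, exist_ok=True)
    table = pd.read_csv(areas_tsv, sep="\t")
    norm = trna.normalize_modifications(table, control=control)
    _write_tsv(norm.levels.reset_index(), outdir / "modification_levels.tsv")
    _write_tsv(norm.relative.reset_index(),
               outdir / "modification_relative.tsv")
    comparison = trna.compare_to_control(norm, n_perm=n_perm, seed=seed)
    _write_tsv(comparison, outdir / "modification_comparison.tsv")
    return {"levels": str(outdir / "modification_levels.tsv"),
            "relative": str(outdir / "modification_relative.tsv"),
            "comparison": str(outdir / "modification_comparison.tsv")}


# ---------------------------------------------------------------------------
# orchestration


def run_pipeline(config: dict | str | Path, outdir: str | Path) -> dict:
    """Execute every stage; return (and write) the run manifest.

    A stage failure stops the run but leaves completed-stage outputs in
    place; the manifest marks the failed stage.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    cfg = validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    sim_cfg = SimConfig.from_dict({"seed": cfg["seed"], **cfg["simulate"]})
    config_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()
    manifest: dict = {"config_hash": config_hash, "seed": cfg["seed"],
                      "derived_seeds": {s: _derived_seed(cfg["seed"], s)
                                        for s in _STAGE_SEED},
                      "stages": {}}

    sim_dir = outdir / "simulated"

    def run_stage(name: str, fn, *args, **kwargs):
        t0 = time.monotonic()
        logger.info("stage %s: seed=%s params=%s", name, cfg["seed"], kwargs)
        try:
            outputs = fn(*args, **kwargs)
        except Exception as exc:
            manifest["stages"][name] = {"status": "failed", "error": str(exc)}
            _write_manifest(manifest, outdir)
            raise
        manifest["stages"][name] = {
            "status": "ok", "outputs": outputs, "params": {
                k: v for k, v in kwargs.items() if not isinstance(v, Path)},
            "wall_time_s": round(time.monotonic() - t0, 3)}
        return outputs

    run_stage("simulate", stage_simulate, sim_cfg, sim_dir)
    run_stage("proteome_de", stage_proteome, sim_dir / "peptides.tsv",
              sim_dir / "peptide_design.tsv", outdir / "proteome",
              trim=cfg["proteome"]["trim"], fdr=cfg["proteome"]["fdr"])
    run_stage("codon_bias", stage_codon, sim_dir / "cds.fasta",
              outdir / "proteome" / "protein_de.tsv", outdir / "codon")
    run_stage("rank_genes", stage_rank, sim_dir / "counts.tsv",
              sim_dir / "count_design.tsv", sim_dir / "rts.tsv",
              outdir / "rank", top_n=cfg["rank"]["top_n"],
              cpm_cutoff=cfg["rank"]["cpm_cutoff"],
              min_samples=cfg["rank"]["min_samples"],
              literal_filter=cfg["rank"]["literal_filter"])
    run_stage("nbs", stage_nbs, sim_dir / "connectomes",
              sim_dir / "connectome_groups.tsv", outdir / "nbs",
              n_perm=cfg["nbs"]["n_perm"],
              seed=_derived_seed(cfg["seed"], "nbs"),
              directions=tuple(cfg["nbs"]["directions"]),
              t_range=tuple(cfg["nbs"]["t_range"]),
              node_labels=sim_dir / "node_labels.txt")
    run_stage("trna_norm", stage_trna, sim_dir / "modification_areas.tsv",
              outdir / "trna", control=cfg["trna"]["control"],
              n_perm=cfg["trna"]["n_perm"],
              seed=_derived_seed(cfg["seed"], "trna"))
    _write_manifest(manifest, outdir)
    return manifest


def _write_manifest(manifest: dict, outdir: Path) -> None:
    with open(Path(outdir) / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)


def hash_outputs(outdir: str | Path) -> dict[str, str]:
    """SHA-256 of every result file (manifest excluded: it records timing)."""
    outdir = Path(outdir)
    hashes = {}
    for path in sorted(outdir.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            hashes[str(path.relative_to(outdir))] = hashlib.sha256(
                path.read_bytes()).hexdigest()
    return hashes
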
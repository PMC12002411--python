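"""Configuration validation and end-to-end orchestration.

A pipeline run executes the stages in dependency order (synthetic data ->
single-cell DE -> reversal enrichment; synthetic data -> bulk TE -> motif ->
truncation), hashing every declared output into a manifest so that a rerun
with the same configuration and seed is verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as ptio
from . import motif as mt
from . import reversal as rv
from . import sc as scmod
from . import te as temod
from . import truncate as tr
from .simulate import (SimConfig, simulate_polysome_experiment,
                       simulate_sc_experiment, simulate_transcripts,
                       synthetic_pathways, write_bulk_dataset,
                       write_ground_truth, write_sc_dataset)

log = logging.getLogger("polytrans")

DEFAULT_THRESHOLDS = {
    "fdr": 0.05,        # BH significance level, all stages
    "lfc_min": 0.2,     # bulk DE |log2FC| floor
    "te_lfc_min": 1.0,  # interaction |log2FC| floor for DTET calls
    "z_min": 3.0,       # hexamer enrichment z floor
    "site_p_max": 0.05, # motif-site exact-p ceiling
    "window": 100,      # truncation window length (nt)
}

_INPUT_KEYS = {"sc_dir", "bulk_counts", "bulk_samples", "fasta", "gmt"}


@dataclass
class PipelineConfig:
    """Validated run configuration: thresholds, seed, and exactly one of a
    synthetic-mode SimConfig or a set of real input paths."""

    outdir: Path
    seed: int = 0
    thresholds: dict = field(default_factory=dict)
    synthetic: SimConfig | None = None
    inputs: dict | None = None
    n_fg: int = 60
    n_bg: int = 60
    log_level: str = "INFO"


def validate_config(doc: dict) -> PipelineConfig:
    """Turn a parsed configuration document into a PipelineConfig.

    Fills threshold defaults, rejects unknown keys, negative thresholds and
    ambiguous modes; raises ValueError with an itemised report.
    """
    errors: list[str] = []
    known = {"outdir", "seed", "thresholds", "synthetic", "inputs",
             "n_fg", "n_bg", "log_level"}
    unknown = set(doc) - known
    if unknown:
        errors.append(f"unknown keys: {sorted(unknown)}")

    thresholds = dict(DEFAULT_THRESHOLDS)
    for key, val in (doc.get("thresholds") or {}).items():
        if key not in DEFAULT_THRESHOLDS:
            errors.append(f"unknown threshold {key!r}")
        elif not isinstance(val, (int, float)) or val <= 0:
            errors.append(f"threshold {key!r} must be positive, got {val!r}")
        else:
            thresholds[key] = val

    synthetic_doc = doc.get("synthetic")
    inputs = doc.get("inputs")
    if (synthetic_doc is None) == (inputs is None):
        errors.append("exactly one of 'synthetic' and 'inputs' must be set")

    sim = None
    if synthetic_doc is not None:
        sim_fields = {f.name for f in dc_fields(SimConfig)}
        bad = set(synthetic_doc) - sim_fields
        if bad:
            errors.append(f"unknown synthetic keys: {sorted(bad)}")
        else:
            try:
                params = dict(synthetic_doc)
                params.setdefault("seed", doc.get("seed", 0))
                for tup_key in ("utr_len_range", "base_probs", "groups"):
                    if tup_key in params:
                        params[tup_key] = tuple(params[tup_key])
                sim = SimConfig(**params).validate()
            except (TypeError, ValueError) as exc:
                errors.append(f"invalid synthetic config: {exc}")

    if inputs is not None:
        bad = set(inputs) - _INPUT_KEYS
        if bad:
            errors.append(f"unknown input keys: {sorted(bad)}")
        for key in _INPUT_KEYS - set(inputs or {}):
            errors.append(f"missing required input path: {key}")
        for key, path in (inputs or {}).items():
            if key in _INPUT_KEYS and not Path(path).exists():
                errors.append(f"input path does not exist: {key}={path}")

    if "outdir" not in doc:
        errors.append("missing required key: outdir")
    if errors:
        raise ValueError("invalid pipeline config:\n  - "
                         + "\n  - ".join(errors))
    return PipelineConfig(outdir=Path(doc["outdir"]),
                          seed=int(doc.get("seed", 0)),
                          thresholds=thresholds, synthetic=sim, inputs=inputs,
                          n_fg=int(doc.get("n_fg", 60)),
                          n_bg=int(doc.get("n_bg", 60)),
                          log_level=str(doc.get("log_level", "INFO")))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(config: PipelineConfig) -> str:
    doc = {"seed": config.seed, "thresholds": config.thresholds,
           "synthetic": None if config.synthetic is None
           else config.synthetic.metadata("sc"),
           "inputs": config.inputs, "n_fg": config.n_fg, "n_bg": config.n_bg}
    return hashlib.sha256(
        json.dumps(doc, sort_keys=True, default=str).encode()).hexdigest()[:12]


def _setup_logging(config: PipelineConfig) -> None:
    config.outdir.mkdir(parents=True, exist_ok=True)
    log.setLevel(getattr(logging, config.log_level.upper(), logging.INFO))
    if not log.handlers:
        log.addHandler(logging.StreamHandler())
    fh = logging.FileHandler(config.outdir / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; return (and write) the run manifest.

    The manifest records the tool version, seed, configuration hash and a
    sha256 per declared output file. A stage failure is recorded and its
    downstream stages are skipped rather than aborting the whole run.
    """
    _setup_logging(config)
    out = config.outdir
    chash = _config_hash(config)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "config_hash": chash, "stages": {}}
    state: dict = {}

    stage_order = ["simulate", "sc_deg", "reversal", "bulk_de", "te",
                   "motif", "truncate"]
    deps = {"simulate": [], "sc_deg": ["simulate"],
            "reversal": ["sc_deg"], "bulk_de": ["simulate"],
            "te": ["bulk_de"], "motif": ["te"], "truncate": ["motif"]}
    runners = {"simulate": _stage_simulate, "sc_deg": _stage_sc_deg,
               "reversal": _stage_reversal, "bulk_de": _stage_bulk_de,
               "te": _stage_te, "motif": _stage_motif,
               "truncate": _stage_truncate}
    failed: set[str] = set()
    for stage in stage_order:
        if any(d in failed for d in deps[stage]):
            manifest["stages"][stage] = {"status": "skipped",
                                         "reason": "upstream failure"}
            failed.add(stage)
            continue
        log.info("stage %s: starting", stage)
        try:
            outputs = runners[stage](config, state, out, chash)
        except Exception as exc:  # recorded, downstream skipped
            log.error("stage %s failed: %s", stage, exc)
            manifest["stages"][stage] = {"status": "failed",
                                         "error": str(exc)}
            failed.add(stage)
            continue
        manifest["stages"][stage] = {
            "status": "ok",
            "outputs": {str(p.relative_to(out)): _sha256(p)
                        for p in sorted(outputs)},
        }
        log.info("stage %s: ok (%d outputs)", stage, len(outputs))
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


# --- stages -----------------------------------------------------------------

def _stage_simulate(config, state, out, chash):
    if config.synthetic is None:
        state["mode"] = "real"
        return _load_real_inputs(config, state)
    sim = config.synthetic
    state["mode"] = "synthetic"
    cm, truth_sc = simulate_sc_experiment(sim)
    bulk, truth_bulk = simulate_polysome_experiment(sim)
    seqs, truth_tx = simulate_transcripts(sim, config.n_fg, config.n_bg)
    collection = synthetic_pathways(truth_sc, sim)
    state.update(cell_matrix=cm, truth_sc=truth_sc, bulk=bulk,
                 truth_bulk=truth_bulk, seqs=seqs, truth_tx=truth_tx,
                 collection=collection)
    scdir = out / "synthetic" / "sc"
    bulkdir = out / "synthetic" / "bulk"
    write_sc_dataset(cm, truth_sc, scdir)
    write_bulk_dataset(bulk, truth_bulk, bulkdir)
    fasta = out / "synthetic" / "transcripts.fasta"
    ptio.write_fasta(seqs, fasta)
    write_ground_truth(truth_tx, out / "synthetic" / "transcripts_truth.tsv")
    gmt = out / "synthetic" / "pathways.gmt"
    ptio.write_gmt(collection, gmt)
    return [scdir / "matrix.mtx", scdir / "cells.tsv", scdir / "genes.tsv",
            scdir / "ground_truth.tsv", bulkdir / "counts.tsv",
            bulkdir / "samples.tsv", bulkdir / "ground_truth.tsv", fasta,
            out / "synthetic" / "transcripts_truth.tsv", gmt]


def _load_real_inputs(config, state):
    paths = config.inputs
    counts, cells, genes = ptio.read_mtx(paths["sc_dir"])
    state["cell_matrix"] = scmod.CellMatrix(counts, cells, genes)
    bc = ptio.read_table(paths["bulk_counts"], index_col=0)
    bs = ptio.read_table(paths["bulk_samples"], index_col=0)
    state["bulk"] = temod.BulkCounts(bc, bs)
    state["seqs"] = ptio.read_fasta(paths["fasta"])
    state["collection"] = ptio.read_gmt(paths["gmt"])
    return []


def _stage_sc_deg(config, state, out, chash):
    th = config.thresholds
    cm, report = scmod.qc_filter_cells(state["cell_matrix"])
    state["cell_matrix_qc"] = cm
    lean, obese, drug = "lean_vehicle", "obese_vehicle", "obese_drug"
    if state["mode"] == "synthetic":
        lean, obese, drug = config.synthetic.groups
    de_ob = scmod.group_de(cm, obese, lean, fdr=th["fdr"])
    de_rosi = scmod.group_de(cm, drug, obese, fdr=th["fdr"])
    state.update(de_ob=de_ob, de_rosi=de_rosi)
    d = out / "sc_deg"
    ptio.write_table(pd.DataFrame([report]), d / "qc_report.tsv", chash)
    ptio.write_table(de_ob, d / "de_obese_vs_lean.tsv", chash)
    ptio.write_table(de_rosi, d / "de_drug_vs_obese.tsv", chash)
    return [d / "qc_report.tsv", d / "de_obese_vs_lean.tsv",
            d / "de_drug_vs_obese.tsv"]


def _stage_reversal(config, state, out, chash):
    th = config.thresholds
    sets = rv.classify_reversal(state["de_ob"], state["de_rosi"],
                                fdr=th["fdr"])
    upset = rv.upset_counts(sets)
    universe = set(state["de_ob"]["gene"]) | set(state["de_rosi"]["gene"])
    d = out / "reversal"
    outputs = []
    for name, genes in (("reversed_up", sets.reversed_up),
                        ("reversed_down", sets.reversed_down)):
        enr = rv.fisher_enrichment(genes & universe, state["collection"],
                                   universe, fdr=th["fdr"],
                                   de=state["de_ob"],
                                   de_secondary=state["de_rosi"]) \
            if genes else pd.DataFrame()
        path = d / f"enrichment_{name}.tsv"
        ptio.write_table(enr, path, chash)
        outputs.append(path)
    sets_df = pd.DataFrame(
        [{"set": k, "genes": ",".join(sorted(v))}
         for k, v in {**sets.as_dict(), "reversed_up": sets.reversed_up,
                      "reversed_down": sets.reversed_down}.items()])
    ptio.write_table(sets_df, d / "reversal_sets.tsv", chash)
    ptio.write_table(upset, d / "upset_counts.tsv", chash)
    state["reversal_sets"] = sets
    return outputs + [d / "reversal_sets.tsv", d / "upset_counts.tsv"]


def _stage_bulk_de(config, state, out, chash):
    th = config.thresholds
    bulk = state["bulk"]
    de_total = temod.nb_de(bulk, "total", padj_max=th["fdr"],
                           lfc_min=th["lfc_min"])
    de_poly = temod.nb_de(bulk, "polysome", padj_max=th["fdr"],
                          lfc_min=th["lfc_min"])
    state.update(de_total=de_total, de_poly=de_poly)
    d = out / "bulk_de"
    ptio.write_table(de_total, d / "de_total.tsv", chash)
    ptio.write_table(de_poly, d / "de_polysome.tsv", chash)
    return [d / "de_total.tsv", d / "de_polysome.tsv"]


def _stage_te(config, state, out, chash):
    th = config.thresholds
    tet = temod.te_interaction(state["bulk"], padj_max=th["fdr"],
                               lfc_min=th["te_lfc_min"])
    labels, venn = temod.classify_translation_mode(state["de_total"],
                                                   state["de_poly"])
    state["te_table"] = tet
    d = out / "te"
    ptio.write_table(tet, d / "te_interaction.tsv", chash)
    ptio.write_table(labels.rename("mode").rename_axis("gene").reset_index(),
                     d / "translation_mode.tsv", chash)
    with open(d / "venn.json", "w") as fh:
        json.dump(venn, fh, indent=2, sort_keys=True)
    return [d / "te_interaction.tsv", d / "translation_mode.tsv",
            d / "venn.json"]


def _stage_motif(config, state, out, chash):
    th = config.thresholds
    regions = ptio.split_regions(state["seqs"])
    d = out / "motif"
    outputs = []
    fg_5utr: dict[str, str] = {}
    model = None
    for region, seqs in regions.items():
        fg = {tx: s for tx, s in seqs.items() if tx.startswith("fg")}
        bg = {tx: s for tx, s in seqs.items() if tx.startswith("bg")}
        if not fg or not bg:
            continue
        kc_fg = mt.count_kmers(fg, label="fg", region=region)
        kc_bg = mt.count_kmers(bg, label="bg", region=region)
        enr = mt.kmer_enrichment_z(kc_fg, kc_bg, z_min=th["z_min"])
        path = d / f"enrichment_{region}.tsv"
        ptio.write_table(enr, path, chash)
        outputs.append(path)
        if region == "5UTR":
            fg_5utr = fg
            enriched = enr.loc[enr["enriched"], "hexamer"].tolist()
            if enriched:
                model = mt.build_pssm(enriched,
                                      background=mt.base_composition(fg))
    if model is not None:
        mpath = d / "pssm_5UTR.txt"
        _write_pssm(model, mpath, chash)
        outputs.append(mpath)
        scans = mt.scan_many(fg_5utr, model, p_max=th["site_p_max"])
        fmap = mt.feature_map(scans)
        sites_rows = [dict(transcript=tx, **row)
                      for tx, df in scans.items()
                      for row in df[df["significant"]].to_dict("records")]
        ptio.write_table(pd.DataFrame(
            sites_rows, columns=["transcript", "start", "score", "p",
                                 "significant"]), d / "sites_5UTR.tsv", chash)
        with open(d / "feature_map.json", "w") as fh:
            json.dump(fmap, fh, indent=2, sort_keys=True)
        outputs += [d / "sites_5UTR.tsv", d / "feature_map.json"]
        state.update(feature_map=fmap, fg_5utr=fg_5utr)
    else:
        state.update(feature_map={}, fg_5utr=fg_5utr)
    return outputs


def _write_pssm(model, path, chash):
    """TRANSFAC-like count matrix text block."""
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"; polytrans v{__version__} config={chash}\n")
        fh.write("PO\tA\tC\tG\tT\n")
        for i, row in enumerate(model.counts, start=1):
            fh.write(f"{i:02d}\t" + "\t".join(f"{int(c)}" for c in row)
                     + "\n")
        fh.write("//\n")


def _stage_truncate(config, state, out, chash):
    th = config.thresholds
    fmap = state.get("feature_map", {})
    lengths = {tx: len(seq) for tx, seq in state.get("fg_5utr", {}).items()}
    table = tr.design_truncated_utrs(
        fmap, {tx: lengths[tx] for tx in fmap}, window=int(th["window"]))
    d = out / "truncate"
    ptio.write_table(table, d / "truncated_utrs.tsv", chash)
    cand = table[table["kind"] == "candidate"]
    bed = cand[["transcript", "start", "end"]].copy()
    bed["name"] = [f"trunc_{i}" for i in range(len(bed))]
    ptio.write_bed(bed, d / "truncated_utrs.bed")
    return [d / "truncated_utrs.tsv", d / "truncated_utrs.bed"]
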
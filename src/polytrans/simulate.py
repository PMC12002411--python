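"""Synthetic inputs with planted ground truth.

Generates every input the downstream stages consume — a three-group single-cell
count matrix, a 2x2 fraction x treatment bulk design, and region-tagged
transcript sequences — as negative-binomial (or i.i.d. base-sampled) draws with
known planted effects, so that recovery and calibration are testable at desk
scale without any external data.

Count law: NB with gene-specific baselines drawn log-normally and a shared
dispersion `alpha`, i.e. Var = mu + alpha * mu^2. Library sizes are
heterogeneous (log-normal(0, 0.2) size factors) so normalisation is
non-trivial. One master seed feeds fixed per-stage child streams, recorded in
the output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as ptio

GROUPS = ("lean_vehicle", "obese_vehicle", "obese_drug")
FRACTIONS = ("total", "polysome")
TREATMENTS = ("vehicle", "drug")
GENE_CLASSES = ("null", "reversed_up", "reversed_down",
                "buffered", "dtet_up", "dtet_down")

# fixed child-stream keys so the three simulators draw from independent
# streams of the same master seed
_STAGE_KEYS = {"sc": 11, "bulk": 23, "tx": 37}


@dataclass
class SimConfig:
    """Parameters of the synthetic experiment family."""

    seed: int = 0
    n_genes: int = 1000
    n_cells_per_group: int = 300
    groups: tuple[str, ...] = GROUPS
    n_reps: int = 3
    dispersion: float = 0.1
    depth_mean: float = 5000.0
    effect_log2fc: float = 2.0
    frac_reversed: float = 0.1
    frac_buffered: float = 0.1
    frac_dtet: float = 0.1
    utr_len_range: tuple[int, int] = (80, 300)
    motif: str = "GGCGGG"
    motif_rate: float = 2.0
    base_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    qc_violation_frac: float = 0.02
    n_marker_genes: int = 0
    n_cell_types: int = 2

    def validate(self) -> "SimConfig":
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        for name in ("n_genes", "n_cells_per_group", "n_reps"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        fracs = (self.frac_reversed, self.frac_buffered, self.frac_dtet)
        if any(f < 0 or f > 1 for f in fracs) or sum(fracs) > 1:
            raise ValueError("class proportions must lie in [0,1] and sum to <= 1")
        if len(self.motif) != 6 or set(self.motif) - set("ACGT"):
            raise ValueError("motif must be a hexamer over {A,C,G,T}")
        lo, hi = self.utr_len_range
        if not (20 <= lo <= hi <= 5000):
            raise ValueError("utr_len_range must lie within [20, 5000]")
        if abs(sum(self.base_probs) - 1.0) > 1e-9 or min(self.base_probs) < 0:
            raise ValueError("base_probs must be a probability vector")
        return self

    def rng(self, stage: str) -> np.random.Generator:
        """Child generator for a named stage of the master seed."""
        return np.random.default_rng([int(self.seed), _STAGE_KEYS[stage]])

    def metadata(self, stage: str) -> dict:
        meta = asdict(self)
        meta["stage"] = stage
        meta["stage_stream"] = [int(self.seed), _STAGE_KEYS[stage]]
        return meta


@dataclass
class GroundTruth:
    """Planted per-gene classes and per-transcript motif positions.

    Classes are mutually exclusive; motif positions are 0-based starts with
    end-exclusive extent (pos .. pos+6).
    """

    gene_classes: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))
    motif_positions: dict[str, list[int]] = field(default_factory=dict)
    marker_genes: dict[str, list[str]] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def genes_of(self, cls: str) -> list[str]:
        return list(self.gene_classes.index[self.gene_classes == cls])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene": self.gene_classes.index,
                             "class": self.gene_classes.values})


def _nb_draws(rng: np.random.Generator, mean: np.ndarray,
              dispersion: float) -> np.ndarray:
    """NB counts with Var = mu + dispersion * mu^2 (gamma-Poisson mixture)."""
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, np.maximum(mean, 1e-12) / shape)
    return rng.poisson(lam)


def _assign_classes(rng: np.random.Generator, genes: pd.Index,
                    config: SimConfig) -> pd.Series:
    n = len(genes)
    n_rev = int(round(config.frac_reversed * n))
    n_buf = int(round(config.frac_buffered * n))
    n_dte = int(round(config.frac_dtet * n))
    picked = rng.choice(n, size=n_rev + n_buf + n_dte, replace=False)
    classes = pd.Series("null", index=genes, dtype=object)
    rev, buf, dte = (picked[:n_rev], picked[n_rev:n_rev + n_buf],
                     picked[n_rev + n_buf:])
    classes.iloc[rev[: (n_rev + 1) // 2]] = "reversed_up"
    classes.iloc[rev[(n_rev + 1) // 2:]] = "reversed_down"
    classes.iloc[buf] = "buffered"
    classes.iloc[dte[: (n_dte + 1) // 2]] = "dtet_up"
    classes.iloc[dte[(n_dte + 1) // 2:]] = "dtet_down"
    return classes


def _baseline_props(rng: np.random.Generator, n_genes: int) -> np.ndarray:
    """Relative expression levels, log-normal across genes, summing to 1."""
    w = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    return w / w.sum()


def simulate_sc_experiment(config: SimConfig):
    """Three-group single-cell NB counts with planted reversal genes.

    Reversed-up genes have their mean multiplied by 2**effect_log2fc in the
    obese-vehicle group relative to lean-vehicle and restored under drug;
    reversed-down genes are symmetric. A `qc_violation_frac` share of cells is
    planted to violate each QC criterion (high mitochondrial fraction, low or
    high depth) so that QC filtering is exercised.

    Returns (CellMatrix, GroundTruth).
    """
    from .sc import CellMatrix  # local import to avoid a cycle

    config.validate()
    rng = config.rng("sc")
    genes = pd.Index([f"gene{i:05d}" for i in range(config.n_genes)])
    classes = _assign_classes(rng, genes, config)

    props = _baseline_props(rng, config.n_genes)
    eff = 2.0 ** config.effect_log2fc
    group_mult = {g: np.ones(config.n_genes) for g in config.groups}
    lean, obese, drug = config.groups
    group_mult[obese] = np.where(classes == "reversed_up", eff,
                                 np.where(classes == "reversed_down",
                                          1.0 / eff, 1.0))
    # bulk-only classes are neutral here; drug restores the lean baseline

    marker_genes: dict[str, list[str]] = {}
    cell_types = [f"type{t}" for t in range(config.n_cell_types)]
    type_mult = {ct: np.ones(config.n_genes) for ct in cell_types}
    if config.n_marker_genes > 0 and config.n_cell_types >= 2:
        null_pool = np.flatnonzero((classes == "null").values)
        mk = rng.choice(null_pool, size=min(config.n_marker_genes,
                                            null_pool.size), replace=False)
        per_type = np.array_split(mk, config.n_cell_types)
        for ct, idx in zip(cell_types, per_type):
            type_mult[ct][idx] = eff
            marker_genes[ct] = list(genes[idx])

    n_cells = config.n_cells_per_group * len(config.groups)
    depth = config.depth_mean * rng.lognormal(0.0, 0.2, size=n_cells)
    mito = rng.beta(2.0, 38.0, size=n_cells)  # typical mito fraction ~5%

    # plant QC violators: high mito, very low depth, very high depth
    n_viol = int(round(config.qc_violation_frac * n_cells))
    if n_viol > 0:
        viol = rng.choice(n_cells, size=min(3 * n_viol, n_cells), replace=False)
        mito[viol[:n_viol]] = rng.uniform(0.26, 0.6, size=n_viol)
        depth[viol[n_viol:2 * n_viol]] = rng.uniform(50, 600, size=n_viol)
        depth[viol[2 * n_viol:3 * n_viol]] = rng.uniform(
            25000, 60000, size=viol.size - 2 * n_viol)

    groups_col, types_col, blocks = [], [], []
    for gi, g in enumerate(config.groups):
        sl = slice(gi * config.n_cells_per_group,
                   (gi + 1) * config.n_cells_per_group)
        cell_depth = depth[sl]
        ct = [cell_types[i % len(cell_types)]
              for i in range(config.n_cells_per_group)]
        mult = np.stack([type_mult[c] for c in ct])  # cells x genes
        mean = cell_depth[:, None] * (props * group_mult[g])[None, :] * mult
        mean *= (props.sum() / (props * group_mult[g] * mult).sum(axis=1,
                                                                  keepdims=True))
        blocks.append(_nb_draws(rng, mean, config.dispersion))
        groups_col += [g] * config.n_cells_per_group
        types_col += ct
    counts = np.vstack(blocks)

    cell_ids = [f"cell{i:05d}" for i in range(n_cells)]
    cells = pd.DataFrame({
        "group": groups_col,
        "cell_type": types_col,
        "umi": counts.sum(axis=1),
        "n_genes": (counts > 0).sum(axis=1),
        "mito_frac": mito,
    }, index=pd.Index(cell_ids, name="cell"))

    truth = GroundTruth(gene_classes=classes, marker_genes=marker_genes,
                        metadata=config.metadata("sc"))
    return CellMatrix(counts=counts, cells=cells, genes=genes), truth


def simulate_polysome_experiment(config: SimConfig):
    """2x2 (fraction x treatment) bulk NB counts with planted TE effects.

    Buffered genes carry `effect_log2fc` in the total-RNA treatment contrast
    but none in the polysome contrast; dtet_up/dtet_down genes carry the
    effect only in the polysome x treatment interaction. Returns
    (BulkCounts, GroundTruth).
    """
    from .te import BulkCounts

    config.validate()
    if config.n_reps < 2:
        raise ValueError("n_reps must be >= 2 (no residual degrees of freedom)")
    rng = config.rng("bulk")
    genes = pd.Index([f"gene{i:05d}" for i in range(config.n_genes)])
    classes = _assign_classes(rng, genes, config)

    props = _baseline_props(rng, config.n_genes)
    eff = 2.0 ** config.effect_log2fc
    is_buf = (classes == "buffered").values
    is_up = (classes == "dtet_up").values
    is_dn = (classes == "dtet_down").values

    sample_rows = []
    cols = {}
    for frac in FRACTIONS:
        for trt in TREATMENTS:
            mult = np.ones(config.n_genes)
            if trt == "drug":
                if frac == "total":
                    mult = np.where(is_buf, eff, 1.0)
                else:
                    mult = np.where(is_up, eff, np.where(is_dn, 1.0 / eff, 1.0))
            for rep in range(1, config.n_reps + 1):
                name = f"{frac}_{trt}_{rep}"
                sf = rng.lognormal(0.0, 0.2)
                mean = config.depth_mean * sf * props * mult
                cols[name] = _nb_draws(rng, mean, config.dispersion)
                sample_rows.append({"sample": name, "fraction": frac,
                                    "treatment": trt, "replicate": rep})
    counts = pd.DataFrame(cols, index=genes)
    samples = pd.DataFrame(sample_rows).set_index("sample")
    truth = GroundTruth(gene_classes=classes,
                        metadata=config.metadata("bulk"))
    return BulkCounts(counts=counts, samples=samples), truth


def _random_seq(rng: np.random.Generator, length: int,
                base_probs) -> np.ndarray:
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=length,
                      p=base_probs)


def _plant_motif(rng: np.random.Generator, seq: np.ndarray, motif: str,
                 n_copies: int) -> list[int]:
    """Overwrite `n_copies` non-overlapping motif instances; returns starts."""
    L = seq.size
    placed: list[int] = []
    motif_arr = np.frombuffer(motif.encode(), dtype="S1")
    for _ in range(n_copies):
        for _attempt in range(200):
            pos = int(rng.integers(0, L - 6 + 1))
            if all(abs(pos - q) >= 6 for q in placed):
                seq[pos:pos + 6] = motif_arr
                placed.append(pos)
                break
    return sorted(placed)


def simulate_transcripts(config: SimConfig, n_fg: int, n_bg: int):
    """Region-tagged transcript sequences with a planted foreground hexamer.

    Foreground 5'UTRs receive Poisson(motif_rate) planted copies of the motif
    at uniform non-overlapping positions; background 5'UTRs, all CDS and all
    3'UTR sequences are i.i.d. draws from `base_probs`. Returns
    ({record_id: sequence}, GroundTruth); foreground transcripts are named
    ``fg####`` and background ``bg####``, with record IDs ``<tx>|<region>``.
    """
    config.validate()
    rng = config.rng("tx")
    lo, hi = config.utr_len_range
    seqs: dict[str, str] = {}
    positions: dict[str, list[int]] = {}
    for label, n_tx, planted in (("fg", n_fg, True), ("bg", n_bg, False)):
        for i in range(n_tx):
            tx = f"{label}{i:04d}"
            utr_len = int(rng.integers(lo, hi + 1))
            utr = _random_seq(rng, utr_len, config.base_probs)
            if planted and config.motif_rate > 0:
                n_copies = int(rng.poisson(config.motif_rate))
                n_copies = min(n_copies, utr_len // 6)
                positions[tx] = _plant_motif(rng, utr, config.motif, n_copies)
            else:
                positions[tx] = []
            cds_len = 3 * int(rng.integers(40, 200))
            utr3_len = int(rng.integers(lo, hi + 1))
            seqs[f"{tx}|5UTR"] = utr.tobytes().decode()
            seqs[f"{tx}|CDS"] = _random_seq(
                rng, cds_len, config.base_probs).tobytes().decode()
            seqs[f"{tx}|3UTR"] = _random_seq(
                rng, utr3_len, config.base_probs).tobytes().decode()
    truth = GroundTruth(motif_positions=positions,
                        metadata=config.metadata("tx"))
    return seqs, truth


def write_ground_truth(truth: GroundTruth, path) -> None:
    """Persist planted classes and motif positions as a single TSV."""
    rows = [{"kind": "gene_class", "id": g, "value": c}
            for g, c in truth.gene_classes.items()]
    rows += [{"kind": "motif_positions", "id": tx,
              "value": ",".join(map(str, pos))}
             for tx, pos in truth.motif_positions.items()]
    rows += [{"kind": "marker_genes", "id": ct, "value": ",".join(gs)}
             for ct, gs in truth.marker_genes.items()]
    ptio.write_table(pd.DataFrame(rows, columns=["kind", "id", "value"]), path)


def read_ground_truth(path) -> GroundTruth:
    # keep_default_na=False: the class label "null" must stay a string
    df = pd.read_csv(path, sep="\t", comment="#", keep_default_na=False)
    gc = df[df["kind"] == "gene_class"].set_index("id")["value"].rename(None)
    gc.index.name = None
    mp = {r["id"]: ([int(x) for x in r["value"].split(",")] if r["value"] else [])
          for _, r in df[df["kind"] == "motif_positions"].iterrows()}
    mk = {r["id"]: (r["value"].split(",") if r["value"] else [])
          for _, r in df[df["kind"] == "marker_genes"].iterrows()}
    return GroundTruth(gene_classes=gc, motif_positions=mp, marker_genes=mk)


def synthetic_pathways(truth: GroundTruth, config: SimConfig,
                       n_random: int = 10,
                       pathway_size: int = 50) -> dict[str, set[str]]:
    """Gene-set collection over the simulated universe.

    One pathway is seeded with the planted reversed genes (padded with nulls)
    so enrichment has a true positive; the rest are random draws.
    """
    rng = np.random.default_rng([int(config.seed), 53])
    genes = list(truth.gene_classes.index)
    planted = truth.genes_of("reversed_up") + truth.genes_of("reversed_down")
    nulls = truth.genes_of("null")
    collection: dict[str, set[str]] = {}
    if planted:
        pad = list(rng.choice(nulls, size=min(len(nulls), pathway_size),
                              replace=False))
        collection["PLANTED_REVERSED"] = set(planted) | set(
            pad[: max(0, pathway_size - len(planted))])
    for i in range(n_random):
        members = rng.choice(genes, size=min(pathway_size, len(genes)),
                             replace=False)
        collection[f"RANDOM_{i:02d}"] = set(members)
    return collection


def write_sc_dataset(matrix, truth: GroundTruth, outdir) -> None:
    outdir = Path(outdir)
    ptio.write_mtx(matrix.counts, matrix.cells, matrix.genes, outdir)
    write_ground_truth(truth, outdir / "ground_truth.tsv")


def write_bulk_dataset(bulk, truth: GroundTruth, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ptio.write_table(bulk.counts, outdir / "counts.tsv", index=True)
    ptio.write_table(bulk.samples, outdir / "samples.tsv", index=True)
    write_ground_truth(truth, outdir / "ground_truth.tsv")
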
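"""Synthetic combination-screen generator with known ground truth.

Emulates the shape of a combination screen: per-(drug pair, cell line)
dose-response matrices over a concentration grid, monotherapy rows, a
percent-growth response scale, and a genes x cells expression matrix with
heterogeneous per-gene variance.

Monotherapy inhibition follows a Hill curve per (drug, cell),
E(d) = Emax * d^h / (EC50^h + d^h) (percent inhibition). Combination
inhibition composes the two monotherapies under Bliss independence,
E12 = E1 + E2 - E1*E2/100, and adds an interaction excess gamma_pc *
g(d1, d2), where gamma_pc is a per-(pair, cell) interaction strength tied
partly to a latent cell factor (so genuinely cell-driven synergies exist)
and g is a unimodal bump peaking mid-grid (so finding the optimal dose
window is a real task). The recorded response is

    response = 100 - E12 - gamma_pc * g(d1, d2) + noise,

clipped to a configurable percent-growth range. Expression is generated
from the same latent cell vectors via random gene loadings plus
heteroscedastic gene noise, so the variance filter and the cell encoder
see realistic structure. The noise-free response of every record and the
gamma of every (pair, cell) ship as a ground-truth sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core_data import (
    Dataset,
    Dialect,
    DrugRecord,
    ExpressionMatrix,
    MeasurementRecord,
    write_drug_table,
    write_expression,
    write_measurements,
)

__all__ = [
    "FIXTURE_SMILES",
    "GeneratorConfig",
    "GroundTruth",
    "generate_dataset",
    "generate_ablation_fixture",
    "write_dataset",
    "load_ground_truth",
]

# Short, valid, drug-like SMILES used as the synthetic compound library.
FIXTURE_SMILES: tuple[str, ...] = (
    "CCO",
    "CC(=O)O",
    "c1ccccc1",
    "Cc1ccccc1",
    "c1ccncc1",
    "c1ccc2ccccc2c1",
    "CC(=O)Nc1ccc(O)cc1",
    "CC(=O)Oc1ccccc1C(=O)O",
    "CN1C=NC2=C1C(=O)N(C)C(=O)N2C",
    "C1CCNCC1",
    "C1CCOC1",
    "CCN(CC)CC",
    "CC(C)Cc1ccc(cc1)C(C)C(=O)O",
    "Clc1ccccc1",
    "Brc1ccccc1",
    "Oc1ccccc1",
    "Nc1ccccc1",
    "COc1ccccc1",
    "CC(N)C(=O)O",
    "NCCc1ccc(O)c(O)c1",
    "OC(=O)c1ccccc1O",
    "CSCC(N)C(=O)O",
    "NC(=O)c1ccccc1",
    "FC(F)(F)c1ccccc1",
    "O=C1CCCCC1",
    "CC1CCCCC1",
    "C1=CC=C(C=C1)C=O",
    "OCC1OC(O)C(O)C(O)C1O",
    "N#Cc1ccccc1",
    "O=S(=O)(N)c1ccccc1",
    "CC(C)(C)c1ccccc1",
    "CCOC(=O)c1ccccc1",
    "Cn1cnc2ccccc21",
    "OCCO",
    "C1CC1",
    "CC=CC(=O)O",
)


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic screen."""

    n_drugs: int = 12
    n_cells: int = 6
    n_pairs: int = 20
    dose_grid: tuple[float, ...] = (1e-8, 1e-7, 1e-6, 1e-5)  # molar, per drug
    n_genes: int = 2000  # pre-filter gene count
    emax_range: tuple[float, float] = (30.0, 95.0)  # percent max inhibition
    ec50_log10_range: tuple[float, float] = (-7.5, -5.5)  # log10 molar
    slope_range: tuple[float, float] = (0.8, 2.5)
    interaction_range: tuple[float, float] = (0.0, 40.0)  # gamma, percent scale
    cell_weight: float = 0.5  # fraction of gamma variation tied to the cell factor
    noise_sd: float = 2.0  # percent-growth measurement noise
    response_clip: tuple[float, float] = (-100.0, 120.0)
    latent_dim: int = 4
    include_monotherapy: bool = True
    seed: int = 0

    def __post_init__(self):
        if min(self.n_drugs, self.n_cells, self.n_pairs, self.n_genes) <= 0:
            raise ValueError("all counts must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_drugs > len(FIXTURE_SMILES):
            raise ValueError(f"at most {len(FIXTURE_SMILES)} fixture drugs available")
        if self.n_pairs > self.n_drugs * (self.n_drugs - 1) // 2:
            raise ValueError("n_pairs exceeds the number of distinct unordered pairs")


@dataclass
class GroundTruth:
    """Noise-free responses per record plus per-(pair, cell) interactions."""

    noise_free: list[float]
    gamma: dict[str, float]  # "drug1|drug2|cell" -> gamma_pc
    tags: dict[str, str] = field(default_factory=dict)  # "drug1|drug2|cell" -> driver tag
    n_clipped: int = 0

    @staticmethod
    def key(d1: str, d2: str, cell: str) -> str:
        a, b = sorted((d1, d2))
        return f"{a}|{b}|{cell}"


def _hill(dose: np.ndarray, emax: float, ec50: float, h: float) -> np.ndarray:
    d = np.asarray(dose, dtype=float)
    return emax * d**h / (ec50**h + d**h)


def _bump(i1: np.ndarray, i2: np.ndarray, n_doses: int) -> np.ndarray:
    """Unimodal interaction surface over grid indices, peaking mid-grid, max 1."""
    if n_doses == 1:
        return np.ones_like(np.asarray(i1, dtype=float))
    p1 = np.asarray(i1, dtype=float) / (n_doses - 1)
    p2 = np.asarray(i2, dtype=float) / (n_doses - 1)
    return np.exp(-((p1 - 0.5) ** 2 + (p2 - 0.5) ** 2) / (2 * 0.2**2))


def _expression(
    rng: np.random.Generator, cfg: GeneratorConfig, z: np.ndarray
) -> ExpressionMatrix:
    """Latent cell vectors x gene loadings + heteroscedastic gene noise."""
    loadings = rng.normal(0.0, 1.0, size=(cfg.n_genes, cfg.latent_dim))
    # informative genes get large loadings; the rest are mostly noise
    informative = rng.random(cfg.n_genes) < 0.3
    loadings[~informative] *= 0.05
    base = rng.normal(5.0, 1.0, size=cfg.n_genes)
    gene_sd = rng.lognormal(mean=-1.0, sigma=0.8, size=cfg.n_genes)
    vals = base[:, None] + loadings @ z.T + rng.normal(size=(cfg.n_genes, cfg.n_cells)) * gene_sd[:, None]
    return ExpressionMatrix(
        gene_ids=[f"G{i:04d}" for i in range(cfg.n_genes)],
        cell_ids=[f"CELL{c}" for c in range(cfg.n_cells)],
        values=vals,
    )


def _build(
    cfg: GeneratorConfig,
    gamma_fn,
    tag_fn=None,
) -> tuple[Dataset, GroundTruth]:
    rng = np.random.default_rng(cfg.seed)
    drug_ids = [f"D{i:02d}" for i in range(cfg.n_drugs)]
    drugs = [DrugRecord(did, FIXTURE_SMILES[i]) for i, did in enumerate(drug_ids)]

    # latent factors: cells and drugs
    z_cell = rng.normal(size=(cfg.n_cells, cfg.latent_dim))
    z_drug = rng.normal(size=(cfg.n_drugs, cfg.latent_dim))
    expr = _expression(rng, cfg, z_cell)
    cell_ids = expr.cell_ids

    # Hill parameters per (drug, cell)
    lo, hi = cfg.emax_range
    emax = rng.uniform(lo, hi, size=(cfg.n_drugs, cfg.n_cells))
    ec50 = 10.0 ** rng.uniform(*cfg.ec50_log10_range, size=(cfg.n_drugs, cfg.n_cells))
    slope = rng.uniform(*cfg.slope_range, size=(cfg.n_drugs, cfg.n_cells))

    all_pairs = [(i, j) for i in range(cfg.n_drugs) for j in range(i + 1, cfg.n_drugs)]
    sel = rng.choice(len(all_pairs), size=cfg.n_pairs, replace=False)
    pairs = [all_pairs[k] for k in sel]

    grid = np.asarray(cfg.dose_grid, dtype=float)
    nd = grid.size
    i1g, i2g = np.meshgrid(np.arange(nd), np.arange(nd), indexing="ij")
    bump = _bump(i1g.ravel(), i2g.ravel(), nd)

    measurements: list[MeasurementRecord] = []
    noise_free: list[float] = []
    gamma_map: dict[str, float] = {}
    tags: dict[str, str] = {}
    clip_lo, clip_hi = cfg.response_clip
    n_clipped = 0

    def emit(d1, d2, dose1, dose2, cell, clean):
        nonlocal n_clipped
        noisy = clean + (rng.normal(0.0, cfg.noise_sd) if cfg.noise_sd > 0 else 0.0)
        clipped = float(np.clip(noisy, clip_lo, clip_hi))
        if clipped != noisy:
            n_clipped += 1
        measurements.append(
            MeasurementRecord(d1, d2, float(dose1), float(dose2), cell, clipped)
        )
        noise_free.append(float(clean))

    for (i, j) in pairs:
        d1_id, d2_id = drug_ids[i], drug_ids[j]
        for c, cell in enumerate(cell_ids):
            g_pc = float(gamma_fn(rng, cfg, i, j, c, z_drug, z_cell))
            key = GroundTruth.key(d1_id, d2_id, cell)
            gamma_map[key] = g_pc
            if tag_fn is not None:
                tags[key] = tag_fn(i, j, c)
            e1 = _hill(grid, emax[i, c], ec50[i, c], slope[i, c])
            e2 = _hill(grid, emax[j, c], ec50[j, c], slope[j, c])
            e12 = e1[i1g.ravel()] + e2[i2g.ravel()] - e1[i1g.ravel()] * e2[i2g.ravel()] / 100.0
            clean = 100.0 - e12 - g_pc * bump
            for k, (a, b) in enumerate(zip(i1g.ravel(), i2g.ravel())):
                emit(d1_id, d2_id, grid[a], grid[b], cell, clean[k])

    if cfg.include_monotherapy:
        used = sorted({i for p in pairs for i in p})
        for i in used:
            for c, cell in enumerate(cell_ids):
                e = _hill(grid, emax[i, c], ec50[i, c], slope[i, c])
                for k, d in enumerate(grid):
                    emit(drug_ids[i], None, d, 0.0, cell, 100.0 - e[k])

    dataset = Dataset(drugs=drugs, measurements=measurements, expression=expr)
    truth = GroundTruth(
        noise_free=noise_free, gamma=gamma_map, tags=tags, n_clipped=n_clipped
    )
    return dataset, truth


def _gamma_mixed(rng, cfg: GeneratorConfig, i, j, c, z_drug, z_cell) -> float:
    """Interaction = pair baseline blended with a cell-factor projection."""
    lo, hi = cfg.interaction_range
    span = hi - lo
    # deterministic in the latent factors so repeated calls for the same
    # (pair, cell) would agree; the pair baseline uses the drug latents too
    u = z_drug[i] + z_drug[j]
    base = lo + span * _sigmoid(u[0])
    cell_term = span * 0.5 * np.tanh(u[1:] @ z_cell[c][1:] / np.sqrt(cfg.latent_dim))
    g = (1 - cfg.cell_weight) * base + cfg.cell_weight * (0.5 * span + cell_term)
    return float(np.clip(g, lo, hi))


def _sigmoid(x: float) -> float:
    return float(1.0 / (1.0 + np.exp(-x)))


def generate_dataset(config: GeneratorConfig) -> tuple[Dataset, GroundTruth]:
    """Generate a full synthetic screen; fixed seed => identical output."""
    return _build(config, _gamma_mixed)


def generate_ablation_fixture(config: GeneratorConfig) -> tuple[Dataset, GroundTruth]:
    """Dataset whose interactions are each driven by exactly one modality.

    Each selected pair is tagged drug1-, drug2- or cell-driven (cycling
    deterministically); its interaction strength is a function of that
    modality's latent factor alone, so e.g. a drug1-driven gamma is
    invariant to substituting the partner drug or the cell line. Tags are
    exported in the ground-truth sidecar for validating the driver
    classifier.
    """
    lo, hi = config.interaction_range
    span = hi - lo

    tag_cycle = ("drug1", "drug2", "cell")

    def tag_fn(i, j, c):
        return tag_cycle[(i + j) % 3]

    def gamma_fn(rng, cfg, i, j, c, z_drug, z_cell):
        tag = tag_fn(i, j, c)
        if tag == "drug1":
            v = z_drug[i][0]
        elif tag == "drug2":
            v = z_drug[j][0]
        else:
            v = z_cell[c][0]
        return lo + span * _sigmoid(2.0 * v)

    return _build(config, gamma_fn, tag_fn)


# ---------------------------------------------------------------------------
# On-disk layout matching the core_data readers, plus the ground-truth sidecar.
# ---------------------------------------------------------------------------


def write_dataset(
    dataset: Dataset,
    truth: GroundTruth,
    out_dir: str | Path,
    dialect: Dialect = Dialect(),
) -> dict[str, str]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "measurements": str(out / "measurements.csv"),
        "drugs": str(out / "drugs.csv"),
        "expression": str(out / "expression.csv"),
        "ground_truth": str(out / "ground_truth.json"),
    }
    write_measurements(dataset.measurements, paths["measurements"], dialect)
    write_drug_table(dataset.drugs, paths["drugs"])
    write_expression(dataset.expression, paths["expression"])
    with open(paths["ground_truth"], "w") as fh:
        json.dump(
            {
                "noise_free": truth.noise_free,
                "gamma": truth.gamma,
                "tags": truth.tags,
                "n_clipped": truth.n_clipped,
            },
            fh,
            indent=1,
        )
    return paths


def load_ground_truth(path: str | Path) -> GroundTruth:
    with open(path) as fh:
        d = json.load(fh)
    return GroundTruth(
        noise_free=[float(x) for x in d["noise_free"]],
        gamma={k: float(v) for k, v in d["gamma"].items()},
        tags=dict(d.get("tags", {})),
        n_clipped=int(d.get("n_clipped", 0)),
    )
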
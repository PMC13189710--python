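"""Input encoders and the fused synergy-prediction model.

Three modalities feed the prediction head:

* drugs — character-level SMILES tokens through an embedding + 1-D CNN,
  giving a learned 128-dimensional molecular representation (ablation
  variants: ECFP circular fingerprints, projected to 128 dims or fed
  folded straight into the head);
* doses — a parameter-free sinusoidal encoding of the (scaled) dose
  position into 64 dimensions, component i being sin(r * 10^(-4i/64)) for
  even i and cos(r * 10^(-4i/64)) for odd i, so the components sweep a
  geometric ladder of frequencies (ablation variant: a learned affine map
  of the scalar dose);
* cell lines — the expression profile of the variance-selected genes
  through a two-layer MLP down to 256 dimensions.

The head concatenates [drug1, drug2, dose1, dose2, cell] and regresses a
single synergy value. Monotherapy rows use the all-pad (index 0) token
sequence for the absent drug — whose embedding is itself learned — and
dose position 0.

Raw molar concentrations (~1e-9..1e-4) would collapse the sinusoid onto
its lowest frequencies, so doses are mapped to a position first; the
default position is -log10(molarity), i.e. 1 uM -> 6.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ._nn import AdamW, Conv1D, Dense, Embedding, Tensor, concat

__all__ = [
    "DOSE_DIM",
    "DRUG_DIM",
    "CELL_DIM",
    "build_vocabulary",
    "ModelConfig",
    "SynergyModel",
    "tokenize_smiles",
    "sinusoidal_encode",
    "dose_position",
    "ecfp_bits",
    "save_model",
    "load_model",
]

DOSE_DIM = 64
DRUG_DIM = 128
CELL_DIM = 256

PAD = 0  # also the null-drug token for monotherapy rows
UNK = 1

# Two-character atom symbols recognised as single tokens.
_TWO_CHAR = ("Cl", "Br", "Si", "Se")
_CHARS = (
    "CNOSPFIBHcnospb"
    "0123456789"
    "()[]=#-+/\\@.%*:"
)


def build_vocabulary() -> dict[str, int]:
    """Fixed token->index map; 0 is pad/null-drug, 1 is unknown."""
    vocab = {"<pad>": PAD, "<unk>": UNK}
    for tok in _TWO_CHAR:
        vocab[tok] = len(vocab)
    for ch in _CHARS:
        vocab[ch] = len(vocab)
    return vocab


def tokenize_smiles(smiles: str, config: "ModelConfig") -> np.ndarray:
    """Character-level tokens (Cl/Br/Si/Se as single tokens), padded/truncated."""
    if not smiles:
        raise ValueError("empty SMILES string")
    vocab = config.vocabulary
    toks: list[int] = []
    i = 0
    while i < len(smiles):
        two = smiles[i : i + 2]
        if two in vocab:
            toks.append(vocab[two])
            i += 2
            continue
        toks.append(vocab.get(smiles[i], UNK))
        i += 1
    out = np.full(config.max_smiles_length, PAD, dtype=np.intp)
    toks = toks[: config.max_smiles_length]
    out[: len(toks)] = toks
    return out


def sinusoidal_encode(dose_position: float | np.ndarray) -> np.ndarray:
    """64-dim sinusoidal encoding of a scalar position (vectorises over arrays).

    Component i is sin(r * f_i) for even i and cos(r * f_i) for odd i with
    f_i = 10^(-4i/64), a strictly decreasing frequency ladder. All
    components lie in [-1, 1] for any finite input.
    """
    r = np.asarray(dose_position, dtype=float)
    if not np.all(np.isfinite(r)):
        raise ValueError("dose position must be finite")
    i = np.arange(DOSE_DIM)
    freq = 10.0 ** (-4.0 * i / DOSE_DIM)
    phase = r[..., None] * freq
    out = np.where(i % 2 == 0, np.sin(phase), np.cos(phase))
    return out


def dose_position(dose_molar: float | np.ndarray, mode: str = "neglog10") -> np.ndarray:
    """Map molar concentration to the encoder's position scale.

    neglog10: position = -log10(dose); a zero dose (monotherapy second
    slot) maps to position 0 by convention. minmax / raw are provided for
    sensitivity checks.
    """
    d = np.asarray(dose_molar, dtype=float)
    if mode == "neglog10":
        with np.errstate(divide="ignore"):
            pos = np.where(d > 0, -np.log10(np.where(d > 0, d, 1.0)), 0.0)
        return pos
    if mode == "minmax":
        pos = np.where(d > 0, d, 0.0)
        span = pos.max() - pos.min() if pos.size > 1 and pos.max() > pos.min() else 1.0
        return 100.0 * (pos - pos.min()) / span
    if mode == "raw":
        return d
    raise ValueError(f"unknown dose scale mode {mode!r}")


def ecfp_bits(smiles: str, radius: int = 2, nbits: int = 1024) -> np.ndarray:
    """Folded circular (Morgan/ECFP) fingerprint as a 0/1 vector."""
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"SMILES does not parse as a molecule: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=nbits)
    return np.array(gen.GetFingerprint(mol), dtype=float)


@dataclass
class ModelConfig:
    """Architecture hyperparameters; everything the checkpoint must replay."""

    vocabulary: dict[str, int] = field(default_factory=build_vocabulary)
    max_smiles_length: int = 80
    n_genes: int = 1000
    token_embed_dim: int = 64
    conv_channels: int = 64
    conv_kernel: int = 5
    n_conv_layers: int = 2
    cell_hidden: int = 512
    head_hidden: tuple[int, ...] = (512, 128)
    dose_scale_mode: str = "neglog10"
    standardize_expression: bool = True  # z-score each gene across cell lines
    center_embeddings: bool = True  # subtract library-mean drug/cell embeddings
    dose_encoding: str = "sin"  # sin | linear
    drug_encoding: str = "cnn"  # cnn | ecfp | ecfp_folded
    ecfp_radius: int = 2
    ecfp_bits: int = 1024
    seed: int = 0

    def drug_out_dim(self) -> int:
        return self.ecfp_bits if self.drug_encoding == "ecfp_folded" else DRUG_DIM

    def head_in_dim(self) -> int:
        return 2 * self.drug_out_dim() + 2 * DOSE_DIM + CELL_DIM

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["head_hidden"] = list(self.head_hidden)
        return d

    @classmethod
    def from_jsonable(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["head_hidden"] = tuple(d["head_hidden"])
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_jsonable(), sort_keys=True).encode()
        ).hexdigest()[:16]

    @classmethod
    def desk(cls, **overrides) -> "ModelConfig":
        """Small CPU-scale architecture (same interface dims, thinner inside)."""
        base = dict(
            n_genes=200,
            token_embed_dim=32,
            conv_channels=32,
            cell_hidden=128,
            head_hidden=(128, 64),
        )
        base.update(overrides)
        return cls(**base)


class SynergyModel:
    """Fused multi-modal dose-response predictor.

    The forward pass is a pure function of (parameters, inputs); with a
    fixed seed, initialisation and therefore training are reproducible.
    """

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        c = config

        if c.drug_encoding == "cnn":
            self.token_embed = Embedding(len(c.vocabulary), c.token_embed_dim, rng)
            self.convs = []
            ch_in = c.token_embed_dim
            for _ in range(c.n_conv_layers):
                self.convs.append(Conv1D(ch_in, c.conv_channels, c.conv_kernel, rng))
                ch_in = c.conv_channels
            self.drug_dense = Dense(c.conv_channels, DRUG_DIM, rng)
        elif c.drug_encoding == "ecfp":
            self.ecfp_proj = Dense(c.ecfp_bits, DRUG_DIM, rng)
        elif c.drug_encoding != "ecfp_folded":
            raise ValueError(f"unknown drug encoding {c.drug_encoding!r}")

        if c.dose_encoding == "linear":
            self.dose_dense = Dense(1, DOSE_DIM, rng)
        elif c.dose_encoding != "sin":
            raise ValueError(f"unknown dose encoding {c.dose_encoding!r}")

        self.cell_h = Dense(c.n_genes, c.cell_hidden, rng)
        self.cell_out = Dense(c.cell_hidden, CELL_DIM, rng)

        self.head_layers = []
        dim = c.head_in_dim()
        for h in c.head_hidden:
            self.head_layers.append(Dense(dim, h, rng))
            dim = h
        self.head_out = Dense(dim, 1, rng)

        # Target standardisation fitted at training time (identity until then).
        self.target_mean = 0.0
        self.target_sd = 1.0
        # Library-mean embeddings (fitted at training time). Centering makes
        # the zero vector represent an "average" drug / cell line, which is
        # what the zero-baseline attribution in `interpret` assumes.
        self.drug_embed_center = np.zeros(config.drug_out_dim())
        self.cell_embed_center = np.zeros(CELL_DIM)

    # -- parameters ------------------------------------------------------
    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        c = self.config
        if c.drug_encoding == "cnn":
            params += self.token_embed.parameters()
            for conv in self.convs:
                params += conv.parameters()
            params += self.drug_dense.parameters()
        elif c.drug_encoding == "ecfp":
            params += self.ecfp_proj.parameters()
        if c.dose_encoding == "linear":
            params += self.dose_dense.parameters()
        params += self.cell_h.parameters() + self.cell_out.parameters()
        for layer in self.head_layers:
            params += layer.parameters()
        params += self.head_out.parameters()
        return params

    # -- modality encoders ------------------------------------------------
    def encode_drugs(self, token_rows: np.ndarray) -> Tensor:
        """(U, L) int tokens -> (U, drug_dim) embeddings (CNN path) or
        fingerprint rows passed through per config for the ECFP paths."""
        c = self.config
        if c.drug_encoding == "cnn":
            if token_rows.shape[1] != c.max_smiles_length:
                raise ValueError(
                    f"token rows length {token_rows.shape[1]} != {c.max_smiles_length}"
                )
            x = self.token_embed(token_rows)  # (U, L, E)
            for conv in self.convs:
                x = conv(x).relu()
            x = x.max(axis=1)  # global max pool over sequence
            return self.drug_dense(x)
        raise ValueError("encode_drugs with token input requires the cnn drug encoding")

    def encode_fingerprints(self, fp_rows: np.ndarray) -> Tensor:
        c = self.config
        if c.drug_encoding == "ecfp":
            return self.ecfp_proj(Tensor(fp_rows))
        if c.drug_encoding == "ecfp_folded":
            return Tensor(np.asarray(fp_rows, dtype=float))
        raise ValueError("fingerprint input requires an ecfp drug encoding")

    def encode_doses(self, positions: np.ndarray) -> Tensor:
        positions = np.asarray(positions, dtype=float)
        if self.config.dose_encoding == "sin":
            return Tensor(sinusoidal_encode(positions))
        return self.dose_dense(Tensor(positions.reshape(-1, 1)))

    def encode_cells(self, expr_cols: np.ndarray) -> Tensor:
        """(U, n_genes) expression rows -> (U, 256)."""
        expr_cols = np.atleast_2d(np.asarray(expr_cols, dtype=float))
        if expr_cols.shape[1] != self.config.n_genes:
            raise ValueError(
                f"expected {self.config.n_genes} genes, got {expr_cols.shape[1]}"
            )
        return self.cell_out(self.cell_h(Tensor(expr_cols)).relu())

    # -- fused forward -----------------------------------------------------
    def head(self, fused: Tensor) -> Tensor:
        """Prediction head on the concatenated embeddings; returns (N,)."""
        x = fused
        for layer in self.head_layers:
            x = layer(x).relu()
        out = self.head_out(x)
        return out.reshape(out.shape[0])

    def forward_indexed(
        self,
        drug_embeds: Tensor,
        d1_idx: np.ndarray,
        d2_idx: np.ndarray,
        cell_embeds: Tensor,
        cell_idx: np.ndarray,
        dose1_pos: np.ndarray,
        dose2_pos: np.ndarray,
        dose_embeds: tuple[Tensor, Tensor] | None = None,
    ) -> Tensor:
        """Forward from pre-encoded unique drugs/cells plus gather indices.

        ``dose_embeds`` lets callers reuse precomputed dose embeddings
        (the sinusoidal encoding is input-only, so a training loop can
        encode each record's doses once).
        """
        e_d1 = drug_embeds.take(np.asarray(d1_idx, dtype=np.intp))
        e_d2 = drug_embeds.take(np.asarray(d2_idx, dtype=np.intp))
        e_c = cell_embeds.take(np.asarray(cell_idx, dtype=np.intp))
        if dose_embeds is None:
            e_r1 = self.encode_doses(dose1_pos)
            e_r2 = self.encode_doses(dose2_pos)
        else:
            e_r1, e_r2 = dose_embeds
        fused = concat([e_d1, e_d2, e_r1, e_r2, e_c], axis=1)
        return self.head(fused)

    def drug_input_rows(self, smiles_list: list[str | None]) -> np.ndarray:
        """Token rows (cnn) or fingerprint rows (ecfp*); None = null drug."""
        c = self.config
        if c.drug_encoding == "cnn":
            rows = np.zeros((len(smiles_list), c.max_smiles_length), dtype=np.intp)
            for i, smi in enumerate(smiles_list):
                if smi is not None:
                    rows[i] = tokenize_smiles(smi, c)
            return rows
        rows = np.zeros((len(smiles_list), c.ecfp_bits))
        for i, smi in enumerate(smiles_list):
            if smi is not None:
                rows[i] = ecfp_bits(smi, c.ecfp_radius, c.ecfp_bits)
        return rows

    def encode_drug_inputs(self, rows: np.ndarray) -> Tensor:
        if self.config.drug_encoding == "cnn":
            return self.encode_drugs(rows)
        return self.encode_fingerprints(rows)

    def predict(
        self,
        smiles1: str,
        smiles2: str | None,
        dose1: float,
        dose2: float,
        expression: np.ndarray,
    ) -> float:
        """Single-sample prediction on the de-standardised response scale."""
        out = self.predict_batch(
            [smiles1, smiles2],
            np.array([0]),
            np.array([1]),
            np.atleast_2d(expression),
            np.array([0]),
            np.array([dose1]),
            np.array([dose2]),
        )
        return float(out[0])

    def predict_batch(
        self,
        unique_smiles: list[str | None],
        d1_idx: np.ndarray,
        d2_idx: np.ndarray,
        unique_expr: np.ndarray,
        cell_idx: np.ndarray,
        dose1: np.ndarray,
        dose2: np.ndarray,
    ) -> np.ndarray:
        rows = self.drug_input_rows(unique_smiles)
        drug_e = self.encode_drug_inputs(rows)
        cell_e = self.encode_cells(unique_expr)
        if self.config.center_embeddings:
            drug_e = drug_e + Tensor(-self.drug_embed_center)
            cell_e = cell_e + Tensor(-self.cell_embed_center)
        pos1 = dose_position(dose1, self.config.dose_scale_mode)
        pos2 = dose_position(dose2, self.config.dose_scale_mode)
        out = self.forward_indexed(drug_e, d1_idx, d2_idx, cell_e, cell_idx, pos1, pos2)
        return out.data * self.target_sd + self.target_mean

    def make_optimizer(self, lr: float, weight_decay: float) -> AdamW:
        return AdamW(self.parameters(), lr=lr, weight_decay=weight_decay)


# ---------------------------------------------------------------------------
# Checkpointing: parameters + full config serialised together.
# ---------------------------------------------------------------------------


def save_model(model: SynergyModel, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {f"p{i}": p.data for i, p in enumerate(model.parameters())}
    arrays["target_stats"] = np.array([model.target_mean, model.target_sd])
    arrays["drug_embed_center"] = model.drug_embed_center
    arrays["cell_embed_center"] = model.cell_embed_center
    meta = {
        "config": model.config.to_jsonable(),
        "config_hash": model.config.config_hash(),
    }
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_model(path: str | Path) -> SynergyModel:
    with np.load(Path(path), allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        config = ModelConfig.from_jsonable(meta["config"])
        if config.config_hash() != meta["config_hash"]:
            raise ValueError("checkpoint config hash mismatch")
        model = SynergyModel(config)
        for i, p in enumerate(model.parameters()):
            p.data = z[f"p{i}"].astype(np.float64)
        stats = z["target_stats"]
        model.target_mean, model.target_sd = float(stats[0]), float(stats[1])
        model.drug_embed_center = z["drug_embed_center"].astype(np.float64)
        model.cell_embed_center = z["cell_embed_center"].astype(np.float64)
    return model
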
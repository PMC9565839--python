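"""3D convolutional autoencoder with feature constructor (CAE-FC).

The encoder maps a two-channel lobule-sized patch through three strided
3D convolutions to a C-channel embedding.  The feature constructor (FC)
scores each embedding channel by the sum of its (non-negative, post-ReLU)
activations, keeps only the highest-scoring channel and zeroes the rest;
the decoder must reconstruct the patch from that single channel.  The
index of the surviving channel is the patch's pattern cluster, so the
same forward pass yields both a compressed representation and an
unsupervised tissue-pattern classification.  The pattern-cluster count C
is chosen by training one model per candidate and keeping the lowest
final reconstruction loss.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._nn import Adam, Conv3d, ConvTranspose3d, ReLU
from .containers import Patch

__all__ = [
    "CaeFcModel",
    "PatchAssignment",
    "feature_construct",
    "train_caefc",
    "select_cluster_count",
    "assign_patches",
]

DEFAULT_CHANNELS = (16, 32)


@dataclass
class PatchAssignment:
    patch_id: int
    cluster_id: int
    activation_strength: float
    flagged: bool = False      # all-zero embedding


def feature_construct(embedding: np.ndarray) -> tuple[np.ndarray, int, float]:
    """Suppress all but the dominant embedding channel.

    ``embedding`` is (C, d, h, w).  The channel score is the sum of
    positive activations; ties resolve to the lowest index.  Returns the
    constructed embedding, the winning channel (= pattern cluster) and
    its score.
    """
    if not np.all(np.isfinite(embedding)):
        raise ValueError("embedding contains non-finite values")
    scores = np.clip(embedding, 0.0, None).sum(axis=(1, 2, 3))
    cluster = int(np.argmax(scores))
    constructed = np.zeros_like(embedding)
    constructed[cluster] = embedding[cluster]
    return constructed, cluster, float(scores[cluster])


def _batch_feature_construct(emb: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(B, C, d, h, w) version; returns constructed, cluster ids, scores."""
    scores = np.clip(emb, 0.0, None).sum(axis=(2, 3, 4))
    clusters = scores.argmax(axis=1)
    mask = np.zeros_like(emb)
    mask[np.arange(emb.shape[0]), clusters] = 1.0
    return emb * mask, clusters, scores[np.arange(emb.shape[0]), clusters]


class CaeFcModel:
    """Trained CAE-FC: layer specs, weights and the assignment rule."""

    def __init__(self, patch_edge: int, n_pattern_clusters: int,
                 channels: tuple[int, ...] = DEFAULT_CHANNELS, seed: int = 0):
        if n_pattern_clusters < 1:
            raise ValueError("need at least one pattern cluster")
        self.patch_edge = int(patch_edge)
        self.C = int(n_pattern_clusters)
        self.channels = tuple(channels)
        self.seed = int(seed)
        self.training_log: list[float] = []
        rng = np.random.default_rng(seed)

        sizes = [self.patch_edge]
        chans = (2,) + self.channels + (self.C,)
        self.encoder: list = []
        for cin, cout in zip(chans[:-1], chans[1:]):
            self.encoder.append(Conv3d(cin, cout, k=3, stride=2, pad=1, rng=rng))
            sizes.append((sizes[-1] + 2 * 1 - 3) // 2 + 1)
            self.encoder.append(ReLU())
        self.embedding_edge = sizes[-1]

        self.decoder: list = []
        rev = chans[::-1]
        rev_sizes = sizes[::-1]
        for i, (cin, cout) in enumerate(zip(rev[:-1], rev[1:])):
            target = rev_sizes[i + 1]
            base = (rev_sizes[i] - 1) * 2 - 2 + 3
            layer = ConvTranspose3d(cin, cout, k=3, stride=2, pad=1,
                                    output_padding=target - base, rng=rng)
            self.decoder.append(layer)
            if i < len(rev) - 2:
                self.decoder.append(ReLU())
        # nudge the embedding conv away from all-dead ReLU channels
        self.encoder[-2].b[:] = 0.05

    # -- forward / backward -------------------------------------------------

    def encode(self, x: np.ndarray) -> np.ndarray:
        for layer in self.encoder:
            x = layer.forward(x)
        return x

    def decode(self, emb: np.ndarray) -> np.ndarray:
        x = emb
        for layer in self.decoder:
            x = layer.forward(x)
        return x

    def forward(self, x: np.ndarray, construct: bool = True):
        emb = self.encode(x)
        if construct:
            constructed, clusters, scores = _batch_feature_construct(emb)
        else:
            constructed, clusters, scores = emb, None, None
        recon = self.decode(constructed)
        return recon, emb, constructed, clusters, scores

    def reconstruction_loss(self, x: np.ndarray, construct: bool = True) -> float:
        recon = self.forward(x, construct=construct)[0]
        return float(np.mean((recon - x) ** 2))

    # -- persistence ---------------------------------------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        spec = {
            "patch_edge": self.patch_edge, "C": self.C,
            "channels": list(self.channels), "seed": self.seed,
            "training_log": self.training_log,
        }
        arrays = {"spec": np.frombuffer(json.dumps(spec).encode(), dtype=np.uint8)}
        for i, layer in enumerate(self.encoder + self.decoder):
            for j, p in enumerate(layer.params):
                arrays[f"p_{i}_{j}"] = p
        np.savez_compressed(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "CaeFcModel":
        with np.load(path) as data:
            spec = json.loads(bytes(data["spec"]).decode())
            model = cls(spec["patch_edge"], spec["C"],
                        tuple(spec["channels"]), spec["seed"])
            model.training_log = list(spec["training_log"])
            for i, layer in enumerate(model.encoder + model.decoder):
                for j in range(len(layer.params)):
                    layer.params[j][...] = data[f"p_{i}_{j}"]
        return model


def _patch_array(patches: list[Patch]) -> np.ndarray:
    shapes = {p.data.shape for p in patches}
    if len(shapes) != 1:
        raise ValueError(f"patches must share shape; got {sorted(shapes)}")
    return np.stack([p.data for p in patches]).astype(np.float32)


def _seed_partition(patches: list[Patch], x_all: np.ndarray, n_clusters: int,
                    seed: int) -> np.ndarray:
    """Initial self-labelling of patches by k-means on standardized
    in-lung channel means (the two-channel summary that defines a
    tissue pattern's average density and Jacobian)."""
    from sklearn.cluster import KMeans
    from sklearn.preprocessing import StandardScaler

    feats = np.empty((len(patches), 2))
    for i, p in enumerate(patches):
        m = p.lung_mask
        if m.any():
            feats[i] = [p.data[0][m].mean(), p.data[1][m].mean()]
        else:
            feats[i] = [p.data[0].mean(), p.data[1].mean()]
    z = StandardScaler().fit_transform(feats)
    return KMeans(n_clusters, n_init=10, random_state=seed).fit(z).labels_


def train_caefc(
    patches: list[Patch],
    n_pattern_clusters: int,
    epochs: int = 30,
    batch_size: int = 32,
    learning_rate: float = 3e-3,
    seed: int = 0,
    channels: tuple[int, ...] = DEFAULT_CHANNELS,
    align_fraction: float = 1.0,
    ce_weight: float = 0.1,
    suppress_weight: float = 0.1,
    mode: str = "caefc",
) -> CaeFcModel:
    """Train the CAE-FC by minimizing mean-squared reconstruction error
    of each patch from its constructed (single-channel) embedding.

    Winner-take-all gating alone collapses onto one channel (only the
    winner ever receives gradient), so training runs in two phases.  An
    alignment phase gates reconstruction by an initial k-means
    self-labelling of the patches and adds (a) a softmax cross-entropy
    pulling each patch's channel-score vector towards its current label
    — applied to the pre-ReLU embedding so silent channels can recover —
    and (b) a suppression penalty on the losing channels' positive
    activations (the FC's "suppress the small activations" made
    explicit).  A free phase then swaps the fixed labels for the model's
    own dominant-channel rule.  ``mode="plain"`` trains an ungated
    autoencoder (full embedding reaches the decoder) for baselines.

    Deterministic under ``seed`` (weight init, self-labelling and batch
    shuffling all derive from it).  Per-epoch mean loss is stored in
    ``model.training_log``.
    """
    if len(patches) < n_pattern_clusters:
        raise ValueError("need at least C patches")
    if mode not in ("caefc", "plain"):
        raise ValueError("mode must be 'caefc' or 'plain'")
    x_all = _patch_array(patches)
    edge = x_all.shape[-1]
    model = CaeFcModel(edge, n_pattern_clusters, channels=channels, seed=seed)
    opt = Adam(model.encoder + model.decoder, lr=learning_rate)
    rng = np.random.default_rng(seed + 1)
    n = len(x_all)
    per_sample = x_all[0].size
    align_epochs = int(round(align_fraction * epochs)) if mode == "caefc" else 0
    labels = (
        _seed_partition(patches, x_all, n_pattern_clusters, seed)
        if align_epochs > 0 else None
    )
    enc_body, enc_relu = model.encoder[:-1], model.encoder[-1]
    for ep in range(epochs):
        phase = "align" if ep < align_epochs else ("plain" if mode == "plain" else "free")
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            xb = x_all[idx]
            B = len(xb)
            pre = xb
            for layer in enc_body:
                pre = layer.forward(pre)
            emb = enc_relu.forward(pre)
            scores = np.clip(emb, 0.0, None).sum(axis=(2, 3, 4))
            if phase == "plain":
                gate = np.ones_like(emb)
            else:
                cl = labels[idx] if phase == "align" else scores.argmax(axis=1)
                gate = np.zeros_like(emb)
                gate[np.arange(B), cl] = 1.0
            recon = model.decode(emb * gate)
            loss = float(np.mean((recon - xb) ** 2))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged (loss={loss}); lower the learning rate"
                )
            d = 2.0 * (recon - xb) / per_sample
            for layer in reversed(model.decoder):
                d = layer.backward(d)
            demb = d * gate
            if phase != "plain":
                demb = demb + suppress_weight * 2.0 * (
                    np.clip(emb, 0.0, None) * (1.0 - gate)
                ) / emb[0].size
            dpre = enc_relu.backward(demb)
            if phase == "align":
                z = scores - scores.max(axis=1, keepdims=True)
                p = np.exp(z)
                p /= p.sum(axis=1, keepdims=True)
                y = np.zeros_like(p)
                y[np.arange(B), labels[idx]] = 1.0
                dpre = dpre + (ce_weight * (p - y))[:, :, None, None, None]
            dx = dpre
            for layer in reversed(enc_body):
                dx = layer.backward(dx)
            opt.step()
            losses.append(loss)
        model.training_log.append(float(np.mean(losses)))
    return model


def select_cluster_count(
    patches: list[Patch],
    candidate_counts: list[int],
    epochs: int = 30,
    batch_size: int = 32,
    learning_rate: float = 3e-3,
    seed: int = 0,
) -> tuple[int, dict[int, float]]:
    """Train one model per candidate C under an identical budget and
    return the candidate with the lowest final training loss, plus the
    full loss table."""
    if len(candidate_counts) < 1:
        raise ValueError("need at least one candidate")
    table: dict[int, float] = {}
    for c in candidate_counts:
        try:
            model = train_caefc(patches, c, epochs=epochs, batch_size=batch_size,
                                learning_rate=learning_rate, seed=seed)
            table[c] = model.training_log[-1]
        except FloatingPointError as err:
            warnings.warn(f"candidate C={c} failed to train: {err}")
    if not table:
        raise RuntimeError("no candidate trained successfully")
    best = min(table, key=table.get)
    return best, table


def assign_patches(model: CaeFcModel, patches: list[Patch],
                   batch_size: int = 256) -> list[PatchAssignment]:
    """Inference-mode cluster assignment: encode, feature-construct,
    take the dominant channel."""
    if not patches:
        return []
    x_all = _patch_array(patches)
    if x_all.shape[-1] != model.patch_edge:
        raise ValueError(
            f"patch edge {x_all.shape[-1]} != model's training edge {model.patch_edge}"
        )
    out: list[PatchAssignment] = []
    for start in range(0, len(x_all), batch_size):
        emb = model.encode(x_all[start:start + batch_size])
        _, clusters, scores = _batch_feature_construct(emb)
        for i, (c, s) in enumerate(zip(clusters, scores)):
            out.append(
                PatchAssignment(
                    patch_id=start + i,
                    cluster_id=int(c),
                    activation_strength=float(s),
                    flagged=bool(s == 0.0),
                )
            )
    return out
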
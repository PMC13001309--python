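"""CIRANO: structure-to-text generation by prefix tuning a frozen causal LM.

A trainable multilayer-perceptron encoder projects a molecular descriptor
vector into ``k`` continuous prefix slots in the token-embedding space of a
frozen causal language model; the language model is conditioned on that
prefix and decodes an odor description.  Gradients flow through the frozen
model into the encoder only: the language model's weights are
fingerprinted and must be byte-identical before and after training.

The LM backend is a contract (:class:`FrozenLM`): the default is a tiny
causal network over a word-level vocabulary whose next-token distribution
at each position depends on the current token and the running mean of all
preceding input embeddings (prefix slots included), so the learned prefix
can steer every decoding step.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from odieu import nn

BOS, EOS, UNK = "<bos>", "<eos>", "<unk>"


@dataclass
class WordTokenizer:
    vocab: tuple[str, ...]

    def __post_init__(self) -> None:
        self._id = {t: i for i, t in enumerate(self.vocab)}

    @classmethod
    def build(cls, texts: Sequence[str]) -> "WordTokenizer":
        from odieu.lexical import tokenize

        words = sorted({t for text in texts for t in tokenize(text)})
        return cls(vocab=(BOS, EOS, UNK, *words))

    @property
    def size(self) -> int:
        return len(self.vocab)

    def encode(self, text: str) -> list[int]:
        from odieu.lexical import tokenize

        unk = self._id[UNK]
        return [self._id.get(t, unk) for t in tokenize(text)]

    def decode(self, ids: Sequence[int]) -> str:
        return " ".join(self.vocab[i] for i in ids
                        if self.vocab[i] not in (BOS, EOS, UNK))


@dataclass
class FrozenLM:
    """Tiny frozen causal language model with a differentiable forward pass.

    h_t = tanh(W1 [e_t ; mean(e_0..e_t) ; p_bar] + b1),
    logits_t = W2 h_t + b2 + beta * p_bar @ token_emb.T,
    where e_i are frozen token embeddings plus frozen positional embeddings,
    prefix slots are supplied as continuous rows, and p_bar is the mean of
    the prefix slots.  The p_bar channel keeps the prefix visible at every
    decoding step instead of being diluted by the growing context (the role
    attention plays in a transformer backbone), and the tied-embedding
    readout term lets the learned prefix raise next-token scores of tokens
    whose embeddings it aligns with.  All parameters are drawn once from
    the seed and never updated.
    """

    tokenizer: WordTokenizer
    embed_dim: int = 16
    hidden_dim: int = 32
    max_len: int = 64
    seed: int = 0
    readout_beta: float = 1.0
    params: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self.params:
            rng = np.random.default_rng(self.seed)
            v, e, h = self.tokenizer.size, self.embed_dim, self.hidden_dim
            self.params = {
                "token_emb": rng.standard_normal((v, e)) * 0.5,
                "pos_emb": rng.standard_normal((self.max_len, e)) * 0.1,
                "w1_cur": rng.standard_normal((e, h)) / np.sqrt(e),
                "w1_ctx": rng.standard_normal((e, h)) / np.sqrt(e),
                "w1_pre": rng.standard_normal((e, h)) / np.sqrt(e),
                "b1": np.zeros(h),
                "w2": rng.standard_normal((h, v)) / np.sqrt(h),
                "b2": np.zeros(v),
            }
        for p in self.params.values():
            p.setflags(write=False)   # enforce the freeze contract at the buffer level

    def fingerprint(self) -> str:
        """SHA-256 over all parameter bytes; invariant across training."""
        digest = hashlib.sha256()
        for name in sorted(self.params):
            digest.update(name.encode())
            digest.update(np.ascontiguousarray(self.params[name]).tobytes())
        return digest.hexdigest()

    # -- differentiable forward -----------------------------------------

    def logits(self, prefix: Optional[nn.Tensor], token_ids: Sequence[int]) -> nn.Tensor:
        """Per-position next-token logits for [prefix slots; tokens]."""
        p = self.params
        tok = nn.Tensor(p["token_emb"][np.asarray(token_ids, int)])
        x = nn.concat_rows([prefix, tok]) if prefix is not None else tok
        t = x.shape[0]
        if t > self.max_len:
            raise ValueError(f"sequence length {t} exceeds max_len {self.max_len}")
        x = x + nn.Tensor(p["pos_emb"][:t])
        # running mean of embeddings up to and including each position
        avg = np.tril(np.ones((t, t))) / np.arange(1, t + 1)[:, None]
        ctx = nn.Tensor(avg) @ x
        pre = x @ nn.Tensor(p["w1_cur"]) + ctx @ nn.Tensor(p["w1_ctx"]) + nn.Tensor(p["b1"])
        out = nn.Tensor(np.zeros((t, self.tokenizer.size)))
        if prefix is not None:
            p_bar = prefix.mean(axis=0, keepdims=True)
            pre = pre + p_bar @ nn.Tensor(p["w1_pre"])
            out = out + p_bar @ nn.Tensor(self.readout_beta * p["token_emb"].T)
        return pre.tanh() @ nn.Tensor(p["w2"]) + nn.Tensor(p["b2"]) + out

    def sequence_loss(self, prefix: Optional[nn.Tensor], text: str) -> nn.Tensor:
        """Teacher-forced mean next-token NLL over the target text (+EOS);
        prefix positions carry no loss."""
        tk = self.tokenizer
        text_ids = tk.encode(text)
        if not text_ids:
            raise ValueError("empty target text")
        ids = [tk._id[BOS], *text_ids, tk._id[EOS]]
        k = 0 if prefix is None else prefix.shape[0]
        logits = self.logits(prefix, ids)
        rows = np.arange(k, k + 1 + len(text_ids))          # BOS..last text token
        targets = np.asarray([*text_ids, tk._id[EOS]], int)  # shifted by one
        lse = nn.logsumexp_rows(logits)
        picked = logits.gather_rows(rows, targets)
        lse_rows = lse.gather_rows(rows, np.zeros(len(rows), dtype=int))
        return (lse_rows - picked).mean()


@dataclass
class PrefixEncoder:
    """4-layer MLP mapping a descriptor vector to k x E prefix slots."""

    input_dim: int
    embed_dim: int
    k: int = 10
    hidden_dim: int = 32
    n_layers: int = 4
    seed: int = 0
    weights: list = field(default_factory=list, repr=False)
    biases: list = field(default_factory=list, repr=False)
    feature_mean: np.ndarray = None
    feature_std: np.ndarray = None

    def __post_init__(self) -> None:
        if not self.weights:
            rng = np.random.default_rng(self.seed)
            dims = [self.input_dim] + [self.hidden_dim] * (self.n_layers - 1) \
                + [self.k * self.embed_dim]
            for d_in, d_out in zip(dims[:-1], dims[1:]):
                self.weights.append(nn.Tensor(
                    rng.standard_normal((d_in, d_out)) / np.sqrt(d_in), requires_grad=True))
                self.biases.append(nn.Tensor(np.zeros(d_out), requires_grad=True))
        if self.feature_mean is None:
            self.feature_mean = np.zeros(self.input_dim)
            self.feature_std = np.ones(self.input_dim)

    @property
    def parameters(self) -> list[nn.Tensor]:
        return [*self.weights, *self.biases]

    def set_standardization(self, descriptors: np.ndarray) -> None:
        """Per-dimension z-score statistics from the training descriptors."""
        self.feature_mean = descriptors.mean(axis=0)
        self.feature_std = np.where(descriptors.std(axis=0) > 0,
                                    descriptors.std(axis=0), 1.0)

    def forward(self, descriptor: np.ndarray) -> nn.Tensor:
        x = np.asarray(descriptor, float)
        if x.shape[-1] != self.input_dim:
            raise ValueError(f"descriptor length {x.shape[-1]} != "
                             f"encoder input dim {self.input_dim}")
        x = (x - self.feature_mean) / self.feature_std
        out = nn.Tensor(x.reshape(1, -1))
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            out = out @ w + b
            if i < len(self.weights) - 1:
                out = out.tanh()
        return out.reshape(self.k, self.embed_dim)

    def state_dict(self) -> dict:
        return {
            "manifest": {"input_dim": self.input_dim, "embed_dim": self.embed_dim,
                         "k": self.k, "hidden_dim": self.hidden_dim,
                         "n_layers": self.n_layers, "seed": self.seed},
            "weights": [w.data.tolist() for w in self.weights],
            "biases": [b.data.tolist() for b in self.biases],
            "feature_mean": self.feature_mean.tolist(),
            "feature_std": self.feature_std.tolist(),
        }

    def save(self, path, lm_fingerprint: str = "") -> None:
        state = self.state_dict()
        state["manifest"]["lm_fingerprint"] = lm_fingerprint
        from pathlib import Path

        Path(path).write_text(json.dumps(state) + "\n")

    @classmethod
    def load(cls, path) -> "PrefixEncoder":
        from pathlib import Path

        state = json.loads(Path(path).read_text())
        m = state["manifest"]
        enc = cls(input_dim=m["input_dim"], embed_dim=m["embed_dim"], k=m["k"],
                  hidden_dim=m["hidden_dim"], n_layers=m["n_layers"], seed=m["seed"])
        for w, data in zip(enc.weights, state["weights"]):
            w.data = np.asarray(data, float)
        for b, data in zip(enc.biases, state["biases"]):
            b.data = np.asarray(data, float)
        enc.feature_mean = np.asarray(state["feature_mean"], float)
        enc.feature_std = np.asarray(state["feature_std"], float)
        return enc


def encode_prefix(encoder: PrefixEncoder, descriptor: np.ndarray) -> np.ndarray:
    """Deterministic forward pass: descriptor -> k x E prefix matrix."""
    out = encoder.forward(descriptor).data
    if not np.isfinite(out).all():
        raise ValueError("non-finite prefix output")
    return out


@dataclass
class TrainConfig:
    epochs: int = 100
    learning_rate: float = 5e-3
    seed: int = 0
    clip_norm: float = 1.0       # global gradient-norm clip; 0 disables
    optimizer: str = "adam"      # "adam" or "sgd" (plain gradient descent)


def train_encoder(
    pairs: Sequence[tuple[np.ndarray, str]],
    lm: FrozenLM,
    encoder: Optional[PrefixEncoder] = None,
    config: TrainConfig = TrainConfig(),
) -> tuple[PrefixEncoder, list[float]]:
    """Minimize next-token NLL of target texts over encoder parameters only.

    Returns the trained encoder and the per-epoch mean-loss trace.  The LM
    fingerprint is checked before and after: any mutation is a hard failure.
    """
    descriptors = np.vstack([np.asarray(d, float) for d, _ in pairs])
    if encoder is None:
        encoder = PrefixEncoder(input_dim=descriptors.shape[1],
                                embed_dim=lm.embed_dim, seed=config.seed)
        encoder.set_standardization(descriptors)
    fp_before = lm.fingerprint()
    if config.optimizer == "sgd":
        opt = nn.SGD(encoder.parameters, lr=config.learning_rate)
    else:
        opt = nn.Adam(encoder.parameters, lr=config.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    trace: list[float] = []
    for _ in range(config.epochs):
        order = rng.permutation(len(pairs))
        total = 0.0
        for i in order:
            descriptor, text = pairs[i]
            opt.zero_grad()
            loss = lm.sequence_loss(encoder.forward(descriptor), text)
            if config.learning_rate > 0:
                loss.backward()
                if config.clip_norm:
                    total = np.sqrt(sum(float((p.grad**2).sum())
                                        for p in encoder.parameters))
                    if total > config.clip_norm:
                        for p in encoder.parameters:
                            p.grad *= config.clip_norm / total
                opt.step()
            total += float(loss.data)
        trace.append(total / len(pairs))
    if lm.fingerprint() != fp_before:
        raise RuntimeError("frozen LM was mutated during training")
    return encoder, trace


@dataclass
class DecodingConfig:
    strategy: str = "greedy"     # "greedy" or "sample"
    max_length: int = 20
    min_length: int = 4          # end-of-sequence suppressed before this many tokens
    seed: int = 0
    temperature: float = 1.0
    #: subtracted from the logit of every already-emitted token; discourages
    #: the degenerate repetition loops greedy decoding is prone to
    repetition_penalty: float = 2.0


def generate(
    encoder: PrefixEncoder,
    descriptor: np.ndarray,
    lm: FrozenLM,
    decoding: DecodingConfig = DecodingConfig(),
) -> str:
    """Decode a description conditioned on the descriptor's learned prefix.

    Greedy decoding is deterministic; an immediate end-of-sequence yields an
    empty string (flagged by the caller, not fatal).
    """
    tk = lm.tokenizer
    prefix = nn.Tensor(encode_prefix(encoder, descriptor))
    ids = [tk._id[BOS]]
    rng = np.random.default_rng(decoding.seed)
    eos = tk._id[EOS]
    for _ in range(decoding.max_length):
        logits = lm.logits(prefix, ids).data[-1].copy()
        logits[tk._id[UNK]] = -np.inf
        logits[tk._id[BOS]] = -np.inf
        if decoding.repetition_penalty:
            for t in ids[1:]:
                logits[t] -= decoding.repetition_penalty
        if len(ids) - 1 < decoding.min_length:
            logits[eos] = -np.inf
        if decoding.strategy == "greedy":
            nxt = int(np.argmax(logits))
        else:
            z = logits / decoding.temperature
            prob = np.exp(z - z.max())
            prob /= prob.sum()
            nxt = int(rng.choice(len(prob), p=prob))
        if nxt == eos:
            break
        ids.append(nxt)
    return tk.decode(ids)
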
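"""Next-frame block forecaster: conv feature extractor -> LSTM -> Gaussian
latent -> coordinate-conditioned generator.

The model predicts a block's next yearly image from its j most recent
frames.  Each scaled frame is compressed by a two-layer convolutional
extractor f into a feature vector; an LSTM consumes the j vectors in order
and its final hidden state is mapped by a parametric Gaussian layer to a
latent code z (reparameterized sample in training, the mean at inference).
A generator G — conditioned by concatenating the block's binary coordinate
code to z — paints the predicted frame through a linear layer and
transposed convolutions, with a sigmoid keeping outputs in [0, 1].

Training minimizes pixel-wise mean squared error between the generated and
true next frame, optionally plus a KL(N(mu, sigma^2) || N(0, 1)) penalty on
the latent layer; there is no adversarial discriminator.  The extractor,
the recurrent encoder (with its Gaussian head), and the generator are held
in three optimizer groups stepped in that order on each minibatch.

The public surface follows the model/results pattern:
``NextFrameForecaster(samples, config).fit()`` returns a
:class:`ForecastResults` carrying the trained parameters, the per-epoch
loss log, prediction and serialization.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from forestcast._autodiff import Adam, Tensor, concat, conv2d, conv_transpose2d
from forestcast.errors import DivergenceError, IncompatibleCheckpointError

_CHECKPOINT_FORMAT = 1


@dataclass(frozen=True)
class ConditionCode:
    """Fixed-width big-endian binary encoding of a block ordinal.

    Ordinal 7 at width 4 encodes as ``0111``; concatenated to the latent
    code, it tells the generator which block of the grid to paint, so one
    model serves the whole grid.
    """

    bits: tuple[int, ...]

    def __post_init__(self):
        if not self.bits or any(b not in (0, 1) for b in self.bits):
            raise ValueError("bits must be a non-empty 0/1 sequence")

    @property
    def width(self) -> int:
        return len(self.bits)

    @property
    def ordinal(self) -> int:
        return int("".join(map(str, self.bits)), 2)

    def __str__(self) -> str:
        return "".join(map(str, self.bits))


def encode_condition(ordinal: int, width: int) -> ConditionCode:
    """Encode a block ordinal as a fixed-width big-endian bit vector."""
    if width < 1:
        raise ValueError("width must be >= 1")
    if not 0 <= ordinal < 2**width:
        raise OverflowError(f"ordinal {ordinal} does not fit in {width} bits")
    return ConditionCode(bits=tuple((ordinal >> (width - 1 - i)) & 1 for i in range(width)))


def condition_width(n_blocks: int) -> int:
    """Bit width needed to address ``n_blocks`` ordinals (minimum 1)."""
    return max(1, int(np.ceil(np.log2(max(n_blocks, 2)))))


@dataclass(frozen=True)
class ForecastConfig:
    """Hyperparameters of the forecaster.

    ``j`` is the input window length in yearly frames; ``itr`` the number
    of training epochs.  ``kl_weight`` 0 leaves a plain reparameterized
    bottleneck; positive values add a KL(N(mu, sigma^2) || N(0,1)) penalty.
    """

    j: int = 3
    frame_size: int = 128
    feature_dim: int = 128
    latent_dim: int = 64
    recurrent_hidden: int = 256
    condition_width: int = 8
    itr: int = 100
    learning_rate: float = 1e-3
    kl_weight: float = 0.0
    batch_size: int = 16
    seed: int = 0

    def __post_init__(self):
        if self.j < 1 or self.itr < 1:
            raise ValueError("j and itr must be >= 1")
        if min(
            self.frame_size,
            self.feature_dim,
            self.latent_dim,
            self.recurrent_hidden,
            self.condition_width,
            self.batch_size,
        ) <= 0:
            raise ValueError("all dimensions must be positive")
        if self.frame_size % 4 != 0:
            raise ValueError("frame_size must be divisible by 4")


@dataclass
class SeriesSample:
    """One training/prediction sample: j scaled input frames and a target."""

    condition: ConditionCode
    inputs: list[np.ndarray]
    target: np.ndarray | None = None

    def __post_init__(self):
        self.inputs = [np.asarray(f, dtype=np.float64) for f in self.inputs]
        if self.target is not None:
            self.target = np.asarray(self.target, dtype=np.float64)


# -- parameter containers --------------------------------------------------

_CONV1_CH = 8
_CONV2_CH = 16
_GEN_CH = 16


def _init_params(config: ForecastConfig, rng: np.random.Generator) -> dict[str, Tensor]:
    """He/Glorot-style initialization of all parameter tensors."""
    fs = config.frame_size
    k = 3
    h1 = (fs - k) // 2 + 1
    h2 = (h1 - k) // 2 + 1
    flat = _CONV2_CH * h2 * h2
    fd, ld, rh, cw = (
        config.feature_dim,
        config.latent_dim,
        config.recurrent_hidden,
        config.condition_width,
    )
    g0 = fs // 4

    def w(*shape, fan_in):
        return Tensor(rng.normal(0.0, np.sqrt(2.0 / fan_in), shape), requires_grad=True)

    def z(*shape):
        return Tensor(np.zeros(shape), requires_grad=True)

    params = {
        # extractor f: two stride-2 convs + linear to feature_dim
        "f.conv1.w": w(_CONV1_CH, 1, k, k, fan_in=k * k),
        "f.conv1.b": z(_CONV1_CH),
        "f.conv2.w": w(_CONV2_CH, _CONV1_CH, k, k, fan_in=_CONV1_CH * k * k),
        "f.conv2.b": z(_CONV2_CH),
        "f.fc.w": w(flat, fd, fan_in=flat),
        "f.fc.b": z(fd),
        # LSTM: input feature_dim, hidden recurrent_hidden, gates i,f,g,o
        "lstm.wx": w(fd, 4 * rh, fan_in=fd),
        "lstm.wh": w(rh, 4 * rh, fan_in=rh),
        "lstm.b": z(4 * rh),
        # Gaussian head
        "head.mu.w": w(rh, ld, fan_in=rh),
        "head.mu.b": z(ld),
        "head.logvar.w": w(rh, ld, fan_in=rh),
        "head.logvar.b": z(ld),
        # generator G: linear + reshape + two transposed convs, sigmoid out
        "g.fc.w": w(ld + cw, _GEN_CH * g0 * g0, fan_in=ld + cw),
        "g.fc.b": z(_GEN_CH * g0 * g0),
        "g.deconv1.w": w(_GEN_CH, _CONV1_CH, 2, 2, fan_in=_GEN_CH),
        "g.deconv1.b": z(_CONV1_CH),
        "g.deconv2.w": w(_CONV1_CH, 1, 2, 2, fan_in=_CONV1_CH),
        "g.deconv2.b": z(1),
    }
    # forget-gate bias starts at 1 so early training retains state
    params["lstm.b"].data[rh : 2 * rh] = 1.0
    return params


def _group_names() -> dict[str, list[str]]:
    return {
        "extractor": ["f.conv1.w", "f.conv1.b", "f.conv2.w", "f.conv2.b", "f.fc.w", "f.fc.b"],
        "encoder": [
            "lstm.wx",
            "lstm.wh",
            "lstm.b",
            "head.mu.w",
            "head.mu.b",
            "head.logvar.w",
            "head.logvar.b",
        ],
        "generator": [
            "g.fc.w",
            "g.fc.b",
            "g.deconv1.w",
            "g.deconv1.b",
            "g.deconv2.w",
            "g.deconv2.b",
        ],
    }


# -- forward pieces --------------------------------------------------------


def _forward_features(frames: Tensor, params: dict[str, Tensor]) -> Tensor:
    """frames (N, 1, fs, fs) -> features (N, feature_dim)."""
    h = conv2d(frames, params["f.conv1.w"], params["f.conv1.b"], stride=2).relu()
    h = conv2d(h, params["f.conv2.w"], params["f.conv2.b"], stride=2).relu()
    n = h.data.shape[0]
    h = h.reshape(n, -1)
    return (h @ params["f.fc.w"] + params["f.fc.b"]).relu()

def _forward_lstm(feature_seq: list[Tensor], params: dict[str, Tensor]) -> Tensor:
    """Ordered feature vectors (each (N, fd)) -> final hidden state (N, rh)."""
    rh = params["lstm.wh"].data.shape[0]
    n = feature_seq[0].data.shape[0]
    h = Tensor(np.zeros((n, rh)))
    c = Tensor(np.zeros((n, rh)))
    for v in feature_seq:
        gates = v @ params["lstm.wx"] + h @ params["lstm.wh"] + params["lstm.b"]
        gi = _slice_cols(gates, 0, rh).sigmoid()
        gf = _slice_cols(gates, rh, 2 * rh).sigmoid()
        gg = _slice_cols(gates, 2 * rh, 3 * rh).tanh()
        go = _slice_cols(gates, 3 * rh, 4 * rh).sigmoid()
        c = gf * c + gi * gg
        h = go * c.tanh()
    return h


def _slice_cols(t: Tensor, a: int, b: int) -> Tensor:
    def backward(g):
        full = np.zeros_like(t.data)
        full[:, a:b] = g
        t._accumulate(full)

    return Tensor(t.data[:, a:b], requires_grad=t.requires_grad, parents=(t,), backward=backward)


def _forward_head(h: Tensor, params: dict[str, Tensor]) -> tuple[Tensor, Tensor]:
    mu = h @ params["head.mu.w"] + params["head.mu.b"]
    logvar = h @ params["head.logvar.w"] + params["head.logvar.b"]
    return mu, logvar


def _forward_generator(z: Tensor, cond: Tensor, params: dict[str, Tensor], frame_size: int) -> Tensor:
    """(z, condition bits) -> frame batch (N, fs, fs) in [0, 1]."""
    g0 = frame_size // 4
    n = z.data.shape[0]
    zc = concat([z, cond], axis=1)
    h = (zc @ params["g.fc.w"] + params["g.fc.b"]).relu()
    h = h.reshape(n, _GEN_CH, g0, g0)
    h = conv_transpose2d(h, params["g.deconv1.w"], params["g.deconv1.b"], stride=2).relu()
    h = conv_transpose2d(h, params["g.deconv2.w"], params["g.deconv2.b"], stride=2)
    return h.reshape(n, frame_size, frame_size).sigmoid()


# -- model / results -------------------------------------------------------


class NextFrameForecaster:
    """Model object: a dataset of SeriesSamples plus a ForecastConfig.

    ``fit()`` runs the training loop and returns a :class:`ForecastResults`.
    """

    def __init__(self, samples: list[SeriesSample], config: ForecastConfig):
        if not samples:
            raise ValueError("dataset must be non-empty")
        for s in samples:
            if len(s.inputs) != config.j:
                raise ValueError(
                    f"sample has {len(s.inputs)} input frames, config.j is {config.j}"
                )
            if s.target is None:
                raise ValueError("training samples need targets")
            if s.condition.width != config.condition_width:
                raise ValueError("condition width mismatch with config")
        self.samples = samples
        self.config = config

    def fit(self, verbose: bool = False) -> "ForecastResults":
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        params = _init_params(cfg, rng)
        groups = _group_names()
        opts = {
            name: Adam([params[p] for p in plist], lr=cfg.learning_rate)
            for name, plist in groups.items()
        }
        n = len(self.samples)
        inputs = np.stack(
            [np.stack(s.inputs) for s in self.samples]
        )  # (n, j, fs, fs)
        targets = np.stack([s.target for s in self.samples])
        conds = np.stack(
            [np.array(s.condition.bits, dtype=np.float64) for s in self.samples]
        )
        log: list[float] = []
        for epoch in range(cfg.itr):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                loss = self._batch_loss(
                    inputs[idx], targets[idx], conds[idx], params, rng, training=True
                )
                for opt in opts.values():
                    opt.zero_grad()
                loss.backward()
                # extractor, encoder+head, generator stepped in order
                opts["extractor"].step()
                opts["encoder"].step()
                opts["generator"].step()
                losses.append(float(loss.data))
            epoch_loss = float(np.mean(losses))
            if not np.isfinite(epoch_loss):
                raise DivergenceError(epoch)
            log.append(epoch_loss)
            if verbose and (epoch % max(1, cfg.itr // 10) == 0 or epoch == cfg.itr - 1):
                print(f"epoch {epoch:4d}  loss {epoch_loss:.6f}")
        return ForecastResults(params=params, config=cfg, training_log=log)

    def _batch_loss(self, inputs, targets, conds, params, rng, training: bool) -> Tensor:
        cfg = self.config
        nb, j, fs, _ = inputs.shape
        frames = Tensor(inputs.reshape(nb * j, 1, fs, fs))
        feats = _forward_features(frames, params)  # (nb*j, fd)
        seq = [
            _slice_rows(feats, t, j) for t in range(j)
        ]  # j tensors of (nb, fd)
        h = _forward_lstm(seq, params)
        mu, logvar = _forward_head(h, params)
        if training:
            eps = rng.standard_normal(mu.data.shape)
            z = mu + (logvar * 0.5).exp() * Tensor(eps)
        else:
            z = mu
        pred = _forward_generator(z, Tensor(conds), params, fs)
        err = pred - Tensor(targets)
        loss = err.square().mean()
        if cfg.kl_weight > 0:
            kl = (mu.square() + logvar.exp() - logvar - 1.0).mean() * 0.5
            loss = loss + kl * cfg.kl_weight
        return loss


def _slice_rows(t: Tensor, offset: int, step: int) -> Tensor:
    """Rows offset, offset+step, ... of a 2-D tensor (frame t of each sample)."""

    def backward(g):
        full = np.zeros_like(t.data)
        full[offset::step] = g
        t._accumulate(full)

    return Tensor(
        t.data[offset::step], requires_grad=t.requires_grad, parents=(t,), backward=backward
    )


class ForecastResults:
    """Fitted forecaster: parameters, config, training log, prediction."""

    def __init__(self, params: dict[str, Tensor], config: ForecastConfig, training_log: list[float]):
        self.params = params
        self.config = config
        self.training_log = training_log

    # -- inference --------------------------------------------------------

    def extract_features(self, frames: list[np.ndarray]) -> list[np.ndarray]:
        """Map scaled frames to feature vectors with the trained extractor."""
        fs = self.config.frame_size
        batch = np.stack([np.asarray(f, dtype=np.float64) for f in frames])
        if batch.shape[1:] != (fs, fs):
            raise ValueError(f"frames must be {fs}x{fs}, got {batch.shape[1:]}")
        out = _forward_features(Tensor(batch[:, None]), self.params)
        return [v for v in out.data]

    def encode_sequence(
        self,
        feature_vectors: list[np.ndarray],
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        """Recurrent pass + Gaussian head; sample z if an rng is given, else mu."""
        seq = [Tensor(np.asarray(v, dtype=np.float64)[None]) for v in feature_vectors]
        h = _forward_lstm(seq, self.params)
        mu, logvar = _forward_head(h, self.params)
        if rng is None:
            return mu.data[0]
        eps = rng.standard_normal(mu.data.shape)
        return (mu.data + np.exp(0.5 * logvar.data) * eps)[0]

    def generate_frame(self, z: np.ndarray, condition: ConditionCode) -> np.ndarray:
        """Paint a frame from a latent code and a block condition code."""
        z = np.asarray(z, dtype=np.float64)
        if z.shape != (self.config.latent_dim,):
            raise ValueError(f"z must have {self.config.latent_dim} entries")
        cond = Tensor(np.array(condition.bits, dtype=np.float64)[None])
        out = _forward_generator(Tensor(z[None]), cond, self.params, self.config.frame_size)
        return out.data[0]

    def predict_next(self, frames: list[np.ndarray], condition: ConditionCode) -> np.ndarray:
        """Deterministic next-frame prediction from the j most recent frames."""
        if len(frames) != self.config.j:
            raise ValueError(f"need exactly {self.config.j} frames, got {len(frames)}")
        feats = self.extract_features(frames)
        z = self.encode_sequence(feats)  # inference: z = mu
        return self.generate_frame(z, condition)

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        cfg = self.config
        n_par = sum(p.data.size for p in self.params.values())
        lines = [
            "Next-frame forecaster (conv extractor -> LSTM -> Gaussian latent -> conditional generator)",
            "=" * 78,
            f"frame size      : {cfg.frame_size}x{cfg.frame_size}",
            f"input window j  : {cfg.j} frames",
            f"feature dim     : {cfg.feature_dim}",
            f"latent dim      : {cfg.latent_dim}  (+{cfg.condition_width} condition bits)",
            f"LSTM hidden     : {cfg.recurrent_hidden}",
            f"parameters      : {n_par}",
            f"epochs trained  : {len(self.training_log)}",
            f"loss first/last : {self.training_log[0]:.6f} / {self.training_log[-1]:.6f}",
            f"kl weight       : {cfg.kl_weight}",
            f"seed            : {cfg.seed}",
        ]
        return "\n".join(lines)

    # -- serialization -----------------------------------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {k.replace(".", "__"): v.data for k, v in self.params.items()}
        with open(path, "wb") as fh:
            np.savez(
                fh,
                __format__=np.array(_CHECKPOINT_FORMAT),
                __config__=np.frombuffer(
                    json.dumps(asdict(self.config)).encode(), dtype=np.uint8
                ),
                __log__=np.array(self.training_log),
                **arrays,
            )

    @classmethod
    def load(cls, path: str | Path) -> "ForecastResults":
        path = Path(path)
        if not path.exists() and path.with_suffix(path.suffix + ".npz").exists():
            path = path.with_suffix(path.suffix + ".npz")
        try:
            data = np.load(path)
        except (OSError, ValueError) as exc:
            raise IncompatibleCheckpointError(f"cannot read checkpoint {path}: {exc}") from exc
        if "__format__" not in data or int(data["__format__"]) != _CHECKPOINT_FORMAT:
            raise IncompatibleCheckpointError(f"unknown checkpoint format in {path}")
        config = ForecastConfig(**json.loads(bytes(data["__config__"]).decode()))
        params = {
            k.replace("__", "."): Tensor(data[k], requires_grad=True)
            for k in data.files
            if not k.startswith("__")
        }
        expected = set(_init_params(config, np.random.default_rng(0)))
        if set(params) != expected:
            raise IncompatibleCheckpointError(
                f"checkpoint parameters do not match config architecture in {path}"
            )
        return cls(params=params, config=config, training_log=[float(x) for x in data["__log__"]])


# -- functional wrappers ---------------------------------------------------


def train(dataset: list[SeriesSample], config: ForecastConfig, verbose: bool = False) -> ForecastResults:
    """Fit the forecaster on a dataset (model/results shorthand)."""
    return NextFrameForecaster(dataset, config).fit(verbose=verbose)


def extract_features(frames: list[np.ndarray], model: ForecastResults) -> list[np.ndarray]:
    return model.extract_features(frames)


def encode_sequence(
    feature_vectors: list[np.ndarray],
    model: ForecastResults,
    seed: int | None = None,
) -> np.ndarray:
    rng = None if seed is None else np.random.default_rng(seed)
    return model.encode_sequence(feature_vectors, rng=rng)


def generate_frame(z: np.ndarray, condition: ConditionCode, model: ForecastResults) -> np.ndarray:
    return model.generate_frame(z, condition)


def predict_next(
    model: ForecastResults, frames: list[np.ndarray], condition: ConditionCode
) -> np.ndarray:
    return model.predict_next(frames, condition)


def save_model(model: ForecastResults, path: str | Path) -> None:
    model.save(path)


def load_model(path: str | Path) -> ForecastResults:
    return ForecastResults.load(path)
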
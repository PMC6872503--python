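"""Bivariate causal discovery with conditional GANs and classifier two-sample tests.

Under an additive-noise view of causation, if X causes Y then Y = f(X, N)
with noise N independent of X, and a conditional generator can reproduce the
distribution of Y from X; the reverse factorization is generally harder to
fit.  The procedure:

1. fit a conditional GAN from X to Y and generate {(x_i, yhat_i)};
2. fit a conditional GAN from Y to X and generate {(xhat_i, y_i)};
3. split into training and test samples;
4. classify real {y_i} against generated {yhat_i} with a K-nearest-neighbor
   classifier; its held-out accuracy is t_xy;
5. likewise classify {x_i} against {xhat_i} to get t_yx;
6. form T = t_xy - t_yx.  Under the null of no causal relationship (or an
   inconclusive test) T is asymptotically N(0, sigma^2) with
   sigma^2 = 0.5 / n_test - 2 cov(t_xy, t_yx).

A lower accuracy means the classifier cannot tell real from generated, i.e.
a better generative fit; significantly negative T therefore favours X -> Y.
The covariance term is estimated from repeated random train/test splits of
the same fitted generators, and sigma^2 is floored at 0.1 / n_test so that a
noisy covariance estimate can never produce a non-positive variance.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.neighbors import KNeighborsClassifier

from . import nn
from .synthetic import ValidationError


def derive_seed(*parts) -> int:
    """Stable sub-stream seed from arbitrary hashable parts (< 2**31)."""
    h = hashlib.sha256()
    for p in parts:
        if isinstance(p, np.ndarray):
            h.update(np.ascontiguousarray(p).tobytes())
        else:
            h.update(repr(p).encode())
    return int.from_bytes(h.digest()[:4], "little") % (2 ** 31)


@dataclass(frozen=True)
class CGANConfig:
    """Conditional GAN hyperparameters.

    The discriminator trains faster than the generator (two-timescale
    learning rates), and the returned generator is an exponential moving
    average of the generator weights along training — both standard
    stabilizers that matter a lot for these small adversarial fits.
    """

    gen_widths: tuple[int, ...] = (32, 32)
    disc_widths: tuple[int, ...] = (32, 32)
    noise_dim: int = 5
    epochs: int = 500
    batch_size: int = 100
    learning_rate: float = 1e-3          # discriminator
    generator_lr: float = 5e-4
    ema_decay: float = 0.998

    def __post_init__(self):
        for name in ("noise_dim", "epochs", "batch_size"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be positive")
        if any(w < 1 for w in self.gen_widths + self.disc_widths):
            raise ValidationError("layer widths must be positive")
        if not 0 <= self.ema_decay < 1:
            raise ValidationError("ema_decay must be in [0, 1)")


#: desk-scale configuration used by the examples and the validation suite
SMALL_CGAN = CGANConfig(epochs=300)


@dataclass
class DirectionFit:
    direction: str                    # "x_to_y" or "y_to_x"
    generator: nn.Sequential
    cause: np.ndarray
    effect: np.ndarray
    generated_effect: np.ndarray      # same length as the input sample
    diagnostics: dict = field(default_factory=dict)


@dataclass
class C2STResult:
    accuracy: float
    n_test: int
    k: int
    seed: int


@dataclass
class CausalTestResult:
    t_xy: float
    t_yx: float
    T: float
    sigma2: float
    z: float
    p_value: float
    call: str                         # x_to_y | y_to_x | inconclusive
    n_test: int
    t_xy_mean: float                  # split-averaged variants, reported
    t_yx_mean: float                  # alongside the single-split statistic
    cov: float


def _mlp(widths, n_in, n_out, rng, hidden):
    layers = []
    prev = n_in
    for w in widths:
        layers.append(nn.Dense(prev, w, rng))
        layers.append(hidden())
        prev = w
    layers.append(nn.Dense(prev, n_out, rng, scale=np.sqrt(1.0 / prev)))
    return nn.Sequential(layers)


def _train_cgan_once(cause, effect, cfg, seed):
    rng = np.random.default_rng(seed)
    gen = _mlp(cfg.gen_widths, 1 + cfg.noise_dim, 1, rng, nn.Tanh)
    disc = _mlp(cfg.disc_widths, 2, 1, rng, lambda: nn.LeakyReLU(0.2))
    g_opt = nn.Adam(gen.params(), lr=cfg.generator_lr, beta1=0.5)
    d_opt = nn.Adam(disc.params(), lr=cfg.learning_rate, beta1=0.5)
    ema = [p.copy() for p, _ in gen.params()]
    n = len(cause)
    d_losses = []
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        for i in range(0, n, cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            xb = cause[idx, None]
            yb = effect[idx, None]
            z = rng.standard_normal((len(idx), cfg.noise_dim))
            fake = gen.forward(np.concatenate([xb, z], axis=1), train=True)
            # discriminator step: real pairs vs generated pairs
            d_in = np.concatenate(
                [np.concatenate([xb, yb], axis=1),
                 np.concatenate([xb, fake], axis=1)])
            targets = np.concatenate([np.ones(len(idx)), np.zeros(len(idx))])
            logits = disc.forward(d_in, train=True)
            d_loss, d_grad = nn.bce_logits_grad(logits, targets)
            disc.backward(d_grad)
            d_opt.step()
            # generator step (non-saturating): push D(x, G(x,z)) towards 1
            z = rng.standard_normal((len(idx), cfg.noise_dim))
            g_in = np.concatenate([xb, z], axis=1)
            fake = gen.forward(g_in, train=True)
            logits = disc.forward(np.concatenate([xb, fake], axis=1), train=True)
            _, g_grad = nn.bce_logits_grad(logits, np.ones(len(idx)))
            d_input_grad = disc.backward(g_grad, need_input_grad=True)
            gen.backward(d_input_grad[:, 1:2])
            g_opt.step()
            for e, (p, _) in zip(ema, gen.params()):
                e *= cfg.ema_decay
                e += (1 - cfg.ema_decay) * p
            d_losses.append(d_loss)
    gen.load_state(ema)
    return gen, float(np.mean(d_losses[-20:])) if d_losses else float("nan")


def fit_cgan(cause, effect, cfg: CGANConfig | None = None, seed: int = 0,
             direction: str = "x_to_y") -> DirectionFit:
    """Fit the conditional generator effect = G(cause, noise).

    Both variables are standardized internally; the generated effects are
    returned on the original scale.  A non-finite training loss triggers one
    seeded retry before raising.
    """
    cfg = cfg or CGANConfig()
    cause = np.asarray(cause, dtype=np.float64).ravel()
    effect = np.asarray(effect, dtype=np.float64).ravel()
    if cause.size != effect.size:
        raise ValidationError("cause and effect must have equal length")
    if cause.size < 20:
        raise ValidationError(f"need n >= 20 samples, got {cause.size}")
    if not (np.all(np.isfinite(cause)) and np.all(np.isfinite(effect))):
        raise ValidationError("inputs must be finite")
    c_sd, e_sd = cause.std(), effect.std()
    if c_sd == 0 and e_sd == 0:
        raise ValidationError("degenerate input: both variables are constant")
    c_mu, e_mu = cause.mean(), effect.mean()
    cs = (cause - c_mu) / (c_sd if c_sd > 0 else 1.0)
    es = (effect - e_mu) / (e_sd if e_sd > 0 else 1.0)

    gen = None
    for attempt in range(2):
        gen, final_d_loss = _train_cgan_once(cs, es, cfg, seed + attempt)
        if np.isfinite(final_d_loss):
            break
        if attempt == 1:
            raise RuntimeError("CGAN training diverged twice; giving up")
    rng = np.random.default_rng(derive_seed(seed, "generate"))
    z = rng.standard_normal((cause.size, cfg.noise_dim))
    fake = gen.forward(np.concatenate([cs[:, None], z], axis=1)).ravel()
    generated = fake * (e_sd if e_sd > 0 else 1.0) + e_mu
    return DirectionFit(direction=direction, generator=gen, cause=cause,
                        effect=effect, generated_effect=generated,
                        diagnostics={"final_d_loss": final_d_loss,
                                     "seed": seed, "cfg": cfg})


def knn_c2st(real, synthetic, k: int | None = None, split_fraction: float = 0.5,
             seed: int = 0) -> C2STResult:
    """Classifier two-sample test accuracy with a K-nearest-neighbor classifier.

    Real points get label 0 and synthetic points label 1; the pooled sample
    is split into train/test with equal label counts per split, and the
    held-out accuracy is the statistic t (0.5 under P = Q).  K defaults to
    floor(sqrt(training size)).
    """
    real = np.atleast_2d(np.asarray(real, dtype=np.float64).T).T
    synthetic = np.atleast_2d(np.asarray(synthetic, dtype=np.float64).T).T
    if real.size == 0 or synthetic.size == 0:
        raise ValidationError("both samples must be non-empty")
    if real.shape[1] != synthetic.shape[1]:
        raise ValidationError("samples must share dimensionality")
    if not 0 < split_fraction < 1:
        raise ValidationError("split_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    tr_idx, te_idx, tr_lab, te_lab = [], [], [], []
    offset = 0
    for lab, data in ((0, real), (1, synthetic)):
        n = len(data)
        perm = rng.permutation(n)
        n_train = int(round(split_fraction * n))
        n_train = min(max(n_train, 1), n - 1)
        tr_idx.append(data[perm[:n_train]])
        te_idx.append(data[perm[n_train:]])
        tr_lab.append(np.full(n_train, lab))
        te_lab.append(np.full(n - n_train, lab))
        offset += n
    X_tr = np.concatenate(tr_idx)
    X_te = np.concatenate(te_idx)
    y_tr = np.concatenate(tr_lab)
    y_te = np.concatenate(te_lab)
    if k is None:
        k = max(1, int(np.sqrt(len(X_tr))))
    if k >= len(X_tr):
        raise ValidationError(f"K={k} must be smaller than training size {len(X_tr)}")
    clf = KNeighborsClassifier(n_neighbors=k)
    clf.fit(X_tr, y_tr)
    acc = float((clf.predict(X_te) == y_te).mean())
    return C2STResult(accuracy=acc, n_test=len(X_te), k=k, seed=seed)


def causal_test(x, y, cfg: CGANConfig | None = None,
                n_covariance_splits: int = 20, seed: int = 0,
                alpha: float = 0.05, k: int | None = None) -> CausalTestResult:
    """Run the full bivariate direction test between two score vectors.

    The two-sample comparisons are made between the real pair dataset
    {(x_i, y_i)} and each generated pair dataset ({(x_i, yhat_i)} for the
    forward direction, {(xhat_i, y_i)} for the reverse) — the joint carries
    the conditional fit that distinguishes the two factorizations.

    The headline t statistics come from the first train/test split; the
    covariance in sigma^2 (and the reported split-averaged t's) come from
    ``n_covariance_splits`` repeated random splits of the same two fitted
    generators.  All sub-stream seeds are derived from the data content, so
    ``causal_test(y, x)`` with the same seed returns exactly -T.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    dx, dy = x.tobytes(), y.tobytes()
    seed_xy = derive_seed(seed, "fit", dx, dy)
    seed_yx = derive_seed(seed, "fit", dy, dx)
    seed_split = derive_seed(seed, "split", *sorted([dx, dy]))

    fit_xy = fit_cgan(x, y, cfg, seed=seed_xy, direction="x_to_y")
    fit_yx = fit_cgan(y, x, cfg, seed=seed_yx, direction="y_to_x")

    real = np.column_stack([x, y])
    gen_xy = np.column_stack([x, fit_xy.generated_effect])
    gen_yx = np.column_stack([fit_yx.generated_effect, y])

    t_xy_s, t_yx_s = [], []
    n_test = None
    for j in range(n_covariance_splits):
        sj = derive_seed(seed_split, j)
        r_xy = knn_c2st(real, gen_xy, k=k, seed=sj)
        r_yx = knn_c2st(real, gen_yx, k=k, seed=sj)
        t_xy_s.append(r_xy.accuracy)
        t_yx_s.append(r_yx.accuracy)
        n_test = r_xy.n_test
    t_xy_s = np.array(t_xy_s)
    t_yx_s = np.array(t_yx_s)
    cov = float(np.cov(t_xy_s, t_yx_s)[0, 1]) if len(t_xy_s) > 1 else 0.0

    t_xy, t_yx = float(t_xy_s[0]), float(t_yx_s[0])
    T = t_xy - t_yx
    sigma2 = max(0.5 / n_test - 2.0 * cov, 0.1 / n_test)
    z = T / np.sqrt(sigma2)
    p = float(2.0 * stats.norm.sf(abs(z)))
    if p < alpha:
        call = "x_to_y" if T < 0 else "y_to_x"
    else:
        call = "inconclusive"
    return CausalTestResult(t_xy=t_xy, t_yx=t_yx, T=T, sigma2=sigma2, z=float(z),
                            p_value=p, call=call, n_test=n_test,
                            t_xy_mean=float(t_xy_s.mean()),
                            t_yx_mean=float(t_yx_s.mean()), cov=cov)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise threshold alpha / m for m tests."""
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    if m < 1:
        raise ValidationError(f"m must be >= 1, got {m}")
    return alpha / m


def parse_p_value(token) -> tuple[float, bool]:
    """Parse a p-value cell; returns (bound, is_upper_bound).

    Censored entries like ``"<0.00005"`` mean the p-value lies in [0, bound).
    """
    if isinstance(token, (int, float)) and not isinstance(token, bool):
        p = float(token)
        if not 0 <= p <= 1:
            raise ValidationError(f"p-value {p} outside [0, 1]")
        return p, False
    text = str(token).strip()
    censored = text.startswith("<")
    try:
        p = float(text[1:] if censored else text)
    except ValueError as e:
        raise ValidationError(f"malformed p-value token {token!r}") from e
    if not 0 <= p <= 1:
        raise ValidationError(f"p-value {p} outside [0, 1]")
    return p, censored


def screen_results(results: pd.DataFrame, threshold: float):
    """Filter a (unit_id, timepoint, p_value) table at a significance threshold.

    Censored entries ``"<b"`` count as significant for any threshold >= b.
    Returns ``(significant_rows, counts_by_timepoint)``; the counts cover
    every timepoint present in the input, including zeros.
    """
    required = {"timepoint", "p_value"}
    if not required <= set(results.columns):
        raise ValidationError(f"results table needs columns {sorted(required)}")
    keep = []
    for i, row in results.iterrows():
        bound, censored = parse_p_value(row["p_value"])
        if censored:
            keep.append(threshold >= bound)
        else:
            keep.append(bound < threshold)
    keep = np.array(keep, dtype=bool)
    filtered = results.loc[keep]
    timepoints = pd.unique(results["timepoint"])
    counts = {tp: int((filtered["timepoint"] == tp).sum()) for tp in timepoints}
    return filtered, counts


def association_test(gene_scores, region_scores, n_permutations: int = 999,
                     seed: int = 0) -> float:
    """Permutation p-value of the first canonical correlation between score sets.

    Rows of one set are permuted; p = (1 + #{perm >= observed}) / (B + 1),
    so the smallest attainable p is 1 / (B + 1).  Subjects are put in a
    canonical (content-sorted) order first, so the p-value does not depend
    on how the input rows happen to be ordered.
    """
    A = _as_score_matrix(gene_scores)
    B = _as_score_matrix(region_scores)
    if A.shape[0] != B.shape[0]:
        raise ValidationError("score sets must cover the same subjects")
    if A.shape[0] < 3:
        raise ValidationError("need at least 3 subjects")
    canon = np.lexsort(np.column_stack([B, A]).T[::-1])
    A, B = A[canon], B[canon]
    rng = np.random.default_rng(seed)
    obs = _first_canonical_correlation(A, B)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(A.shape[0])
        if _first_canonical_correlation(A, B[perm]) >= obs:
            count += 1
    return (1 + count) / (n_permutations + 1)


def _as_score_matrix(scores) -> np.ndarray:
    arr = getattr(scores, "scores", scores)
    arr = np.asarray(arr, dtype=np.float64)
    return arr[:, None] if arr.ndim == 1 else arr


def _first_canonical_correlation(A: np.ndarray, B: np.ndarray) -> float:
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)
    Qa, _ = np.linalg.qr(Ac)
    Qb, _ = np.linalg.qr(Bc)
    s = np.linalg.svd(Qa.T @ Qb, compute_uv=False)
    return float(min(s.max(initial=0.0), 1.0))
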
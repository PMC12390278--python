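"""Component-wise random-walk Metropolis-within-Gibbs sampler.

All parameters are sampled on the natural-log (or otherwise unbounded)
scale.  Each coordinate has its own Gaussian proposal scale, adapted
during burn-in by a diminishing Robbins-Monro rule towards a target
acceptance rate and frozen afterwards, so the post-burn-in chain is a
valid Markov chain.  Convergence is monitored with the Gelman-Rubin
potential scale reduction factor computed from between- and within-chain
variances of the post-burn-in draws (classic whole-chain variant; the
split variant is available behind a flag).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Target",
    "GroupMove",
    "GibbsMove",
    "CallableTarget",
    "SamplerConfig",
    "PosteriorSamples",
    "run_chains",
    "rhat",
    "convergence_report",
]


class Target:
    """Log-density interface the sampler consumes.

    Subclasses must set ``dim`` and ``names`` and implement
    :meth:`logp`.  :meth:`coord_logp` may return only the terms of the
    log-density that depend on coordinate ``i``; the default falls back
    to the full density, which is always correct but may be slow.
    """

    dim: int
    names: list[str]

    def logp(self, x: np.ndarray) -> float:  # pragma: no cover - interface
        raise NotImplementedError

    def coord_logp(self, x: np.ndarray, i: int) -> float:
        return self.logp(x)


class GroupMove:
    """A joint proposal over several coordinates with its own scale.

    Targets may return a list of these from a ``group_moves()`` method;
    the sampler applies each once per iteration after the coordinate
    scan.  Interweaving moves of this kind (translating a population
    mean together with its individual effects, or rescaling the spread
    of the effects together with the population variance) break the slow
    random-walk coupling of hierarchical posteriors.
    """

    name: str
    #: execute the move on every ``stride``-th iteration only (an
    #: expensive move can still help mixing when applied periodically)
    stride: int = 1
    #: acceptance rate the scale adaptation aims for (multivariate moves
    #: should target ~0.25, scalar moves ~0.44)
    target_accept: float | None = None
    #: starting proposal scale (falls back to the sampler default)
    initial_scale: float | None = None

    def propose(self, x: np.ndarray, scale: float, rng):  # pragma: no cover
        """Return (proposed vector, log absolute Jacobian determinant).

        All randomness must come from ``rng`` so runs stay reproducible.
        """
        raise NotImplementedError

    def logp(self, x: np.ndarray) -> float:  # pragma: no cover - interface
        """Terms of the log-density affected by this move."""
        raise NotImplementedError

    def reset(self) -> None:
        """Clear any per-chain adaptation state (called at chain start)."""

    def adapt(self, x: np.ndarray) -> None:
        """Observe the burn-in state (called once per burn-in iteration)."""


class GibbsMove:
    """A move that samples (a Metropolized approximation of) a full
    conditional itself instead of using a scaled random-walk proposal.

    ``update`` returns the new state vector together with the number of
    internal proposals made and accepted; the engine applies it as-is,
    with no scale adaptation.
    """

    name: str
    stride: int = 1

    def reset(self) -> None:
        """Clear any per-chain state (called at chain start)."""

    def update(self, x: np.ndarray, rng):  # pragma: no cover - interface
        """Return (new state vector, n_proposed, n_accepted)."""
        raise NotImplementedError


class CallableTarget(Target):
    """Wrap a plain ``logp(x)`` callable as a :class:`Target`."""

    def __init__(self, fn, dim: int, names: list[str] | None = None):
        self._fn = fn
        self.dim = dim
        self.names = names if names is not None else [f"x{i}" for i in range(dim)]

    def logp(self, x: np.ndarray) -> float:
        return float(self._fn(x))


@dataclass
class SamplerConfig:
    """Sampler settings.

    ``n_iter`` counts total iterations per chain including burn-in;
    ``burn_in_frac`` of them are discarded (and used for proposal
    adaptation).  Scales adapt in windows of ``adapt_window`` iterations
    with a step shrinking as 1/sqrt(window index) towards
    ``target_accept``.
    """

    n_chains: int = 4
    n_iter: int = 11000
    burn_in_frac: float = 0.5
    thin: int = 1
    initial_scale: float = 0.1
    adapt_window: int = 50
    target_accept: float = 0.44
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if not (0.0 <= self.burn_in_frac < 1.0):
            raise ValueError("burn_in_frac must lie in [0, 1)")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if not (0.0 < self.target_accept < 1.0):
            raise ValueError("target_accept must lie in (0, 1)")

    @property
    def n_burn(self) -> int:
        return int(self.n_iter * self.burn_in_frac)


@dataclass
class PosteriorSamples:
    """Posterior draws and sampler diagnostics.

    ``draws`` has shape ``(n_chains, n_stored, dim)`` and contains every
    stored iteration (burn-in included; ``n_burn_stored`` of them).
    ``accept_rate`` is the post-burn-in acceptance rate per chain and
    coordinate; ``scale_history`` holds one proposal-scale snapshot per
    adaptation window so the freeze after burn-in is auditable.
    """

    draws: np.ndarray
    names: list[str]
    n_burn_stored: int
    accept_rate: np.ndarray
    scales: np.ndarray
    scale_history: np.ndarray
    config: SamplerConfig
    move_names: list[str] = field(default_factory=list)
    move_accept_rate: np.ndarray | None = None

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def dim(self) -> int:
        return self.draws.shape[2]

    def index_of(self, parameter: str) -> int:
        try:
            return self.names.index(parameter)
        except ValueError:
            raise KeyError(f"unknown parameter {parameter!r}") from None

    def post_burn_in(self) -> np.ndarray:
        """Draws after burn-in, shape (n_chains, n_kept, dim)."""
        return self.draws[:, self.n_burn_stored :, :]

    def pooled(self, parameter: str | int | None = None) -> np.ndarray:
        """Post-burn-in draws pooled across chains."""
        post = self.post_burn_in()
        flat = post.reshape(-1, self.dim)
        if parameter is None:
            return flat
        i = parameter if isinstance(parameter, int) else self.index_of(parameter)
        return flat[:, i]

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format table (chain, iteration, parameter, value)."""
        n_chains, n_stored, dim = self.draws.shape
        chain = np.repeat(np.arange(n_chains), n_stored * dim)
        iteration = np.tile(np.repeat(np.arange(n_stored), dim), n_chains)
        parameter = np.tile(np.array(self.names), n_chains * n_stored)
        return pd.DataFrame(
            {
                "chain": chain,
                "iteration": iteration,
                "parameter": parameter,
                "value": self.draws.reshape(-1),
            }
        )

    @classmethod
    def from_long_frame(
        cls, frame: pd.DataFrame, n_burn_stored: int, config: SamplerConfig | None = None
    ) -> "PosteriorSamples":
        names = list(dict.fromkeys(frame["parameter"]))
        chains = sorted(frame["chain"].unique())
        dim = len(names)
        n_stored = frame["iteration"].nunique()
        draws = np.empty((len(chains), n_stored, dim))
        pivot_names = {n: k for k, n in enumerate(names)}
        for c_idx, c in enumerate(chains):
            sub = frame[frame["chain"] == c]
            piv = sub.pivot(index="iteration", columns="parameter", values="value")
            cols = sorted(piv.columns, key=lambda n: pivot_names[n])
            draws[c_idx] = piv[cols].to_numpy()
        return cls(
            draws=draws,
            names=names,
            n_burn_stored=n_burn_stored,
            accept_rate=np.full((len(chains), dim), np.nan),
            scales=np.full(dim, np.nan),
            scale_history=np.empty((len(chains), 0, dim)),
            config=config if config is not None else SamplerConfig(),
        )


def _resolve_inits(target: Target, config: SamplerConfig, init) -> list[np.ndarray]:
    if callable(init):
        rngs = [
            np.random.default_rng(np.random.SeedSequence([config.seed, c, 77]))
            for c in range(config.n_chains)
        ]
        return [np.asarray(init(c, rngs[c]), dtype=float) for c in range(config.n_chains)]
    arr = np.asarray(init, dtype=float)
    if arr.ndim == 1:
        return [arr.copy() for _ in range(config.n_chains)]
    if arr.ndim == 2 and arr.shape[0] == config.n_chains:
        return [arr[c].copy() for c in range(config.n_chains)]
    raise ValueError("init must be a vector, a (n_chains, dim) array, or a callable")


def run_chains(model, config: SamplerConfig, init) -> PosteriorSamples:
    """Run independent Metropolis-within-Gibbs chains.

    ``model`` is a :class:`Target` or a plain log-posterior callable (in
    which case ``init`` must determine the dimension).  ``init`` is a
    starting vector shared by all chains, one vector per chain, or a
    callable ``init(chain_index, rng) -> x0``.  Draws are bitwise
    reproducible for a fixed :attr:`SamplerConfig.seed`.
    """
    inits = None
    if not isinstance(model, Target):
        inits = _resolve_inits_dimless(config, init)
        model = CallableTarget(model, dim=inits[0].size)
    target = model
    if inits is None:
        inits = _resolve_inits(target, config, init)

    bad = []
    for c, x0 in enumerate(inits):
        if x0.shape != (target.dim,):
            raise ValueError(
                f"chain {c} init has shape {x0.shape}, expected ({target.dim},)"
            )
        if not np.isfinite(target.logp(x0)):
            bad.append(c)
    if bad:
        raise ValueError(
            f"log-posterior not finite at the initial point of chains {bad}"
        )

    moves = list(target.group_moves()) if hasattr(target, "group_moves") else []
    n_moves = len(moves)

    n_stored = config.n_iter // config.thin
    n_burn_stored = config.n_burn // config.thin
    draws = np.empty((config.n_chains, n_stored, target.dim))
    accept_rate = np.empty((config.n_chains, target.dim))
    move_accept_rate = np.empty((config.n_chains, n_moves))
    n_windows = max(1, config.n_burn // config.adapt_window)
    scale_history = np.empty((config.n_chains, n_windows, target.dim))
    final_scales = np.empty((config.n_chains, target.dim))

    move_targets = np.array(
        [
            getattr(m, "target_accept", None) or config.target_accept
            for m in moves
        ]
    )

    for c in range(config.n_chains):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, c]))
        x = inits[c].copy()
        scales = np.full(target.dim, config.initial_scale)
        move_scales = np.array(
            [
                getattr(m, "initial_scale", None) or config.initial_scale
                for m in moves
            ]
        )
        for move in moves:
            move.reset()
        win_accepts = np.zeros(target.dim)
        win_move_accepts = np.zeros(n_moves)
        win_move_execs = np.zeros(n_moves)
        post_accepts = np.zeros(target.dim)
        post_move_accepts = np.zeros(n_moves)
        post_move_execs = np.zeros(n_moves)
        n_post = 0
        window = 0
        stored = 0
        for it in range(config.n_iter):
            in_burn = it < config.n_burn
            # draw per-iteration randomness in a fixed order for determinism
            steps = rng.standard_normal(target.dim)
            log_us = np.log(rng.random(target.dim))
            for i in range(target.dim):
                lp_cur = target.coord_logp(x, i)
                old = x[i]
                x[i] = old + scales[i] * steps[i]
                lp_prop = target.coord_logp(x, i)
                if log_us[i] < lp_prop - lp_cur:
                    if in_burn:
                        win_accepts[i] += 1
                    else:
                        post_accepts[i] += 1
                else:
                    x[i] = old
            for g, move in enumerate(moves):
                if it % move.stride:
                    continue
                if isinstance(move, GibbsMove):
                    x, n_prop, n_acc = move.update(x, rng)
                    if in_burn:
                        win_move_execs[g] += n_prop
                        win_move_accepts[g] += n_acc
                    else:
                        post_move_execs[g] += n_prop
                        post_move_accepts[g] += n_acc
                    continue
                if in_burn:
                    win_move_execs[g] += 1
                else:
                    post_move_execs[g] += 1
                x_prop, log_jac = move.propose(x, move_scales[g], rng)
                lp_cur = move.logp(x)
                lp_prop = move.logp(x_prop)
                if math.log(rng.random()) < lp_prop - lp_cur + log_jac:
                    x = x_prop
                    if in_burn:
                        win_move_accepts[g] += 1
                    else:
                        post_move_accepts[g] += 1
            if in_burn:
                for move in moves:
                    if not isinstance(move, GibbsMove):
                        move.adapt(x)
            if not in_burn:
                n_post += 1
            if in_burn and (it + 1) % config.adapt_window == 0:
                rate = win_accepts / config.adapt_window
                window += 1
                step = min(1.0, 2.0 / math.sqrt(window))
                scales *= np.exp(step * (rate - config.target_accept))
                if n_moves:
                    move_rate = win_move_accepts / np.maximum(1.0, win_move_execs)
                    move_scales *= np.exp(step * (move_rate - move_targets))
                    win_move_accepts[:] = 0.0
                    win_move_execs[:] = 0.0
                if window <= n_windows:
                    scale_history[c, window - 1] = scales
                win_accepts[:] = 0.0
            if (it + 1) % config.thin == 0:
                draws[c, stored] = x
                stored += 1
        # pad unused windows with the final scales
        for w in range(window, n_windows):
            scale_history[c, w] = scales
        final_scales[c] = scales
        accept_rate[c] = post_accepts / max(1, n_post)
        move_accept_rate[c] = post_move_accepts / np.maximum(1.0, post_move_execs)

    return PosteriorSamples(
        draws=draws,
        names=list(target.names),
        n_burn_stored=n_burn_stored,
        accept_rate=accept_rate,
        scales=final_scales.mean(axis=0),
        scale_history=scale_history,
        config=config,
        move_names=[m.name for m in moves],
        move_accept_rate=move_accept_rate,
    )


def _resolve_inits_dimless(config: SamplerConfig, init) -> list[np.ndarray]:
    if callable(init):
        raise ValueError(
            "a callable init requires a Target with a declared dimension"
        )
    arr = np.asarray(init, dtype=float)
    if arr.ndim == 1:
        return [arr.copy() for _ in range(config.n_chains)]
    if arr.ndim == 2 and arr.shape[0] == config.n_chains:
        return [arr[c].copy() for c in range(config.n_chains)]
    raise ValueError("init must be a vector or a (n_chains, dim) array")


def rhat(
    samples: PosteriorSamples,
    parameter: str | int,
    split: bool = False,
) -> float:
    """Gelman-Rubin potential scale reduction factor for one parameter.

    Computed from whole post-burn-in chains (``split=True`` halves each
    chain first).  Chains that are all identical constants give 1.0 by
    convention.
    """
    i = parameter if isinstance(parameter, int) else samples.index_of(parameter)
    post = samples.post_burn_in()[:, :, i]
    if post.shape[0] < 2:
        raise ValueError("rhat requires at least 2 chains")
    if split:
        half = post.shape[1] // 2
        post = np.concatenate([post[:, :half], post[:, half : 2 * half]], axis=0)
    m, n = post.shape
    if n < 10:
        raise ValueError(f"rhat requires >= 10 post-burn-in draws, got {n}")
    chain_means = post.mean(axis=1)
    chain_vars = post.var(axis=1, ddof=1)
    w = chain_vars.mean()
    if w == 0.0:
        return 1.0
    b = n * chain_means.var(ddof=1)
    var_hat = (n - 1) / n * w + b / n
    return float(math.sqrt(var_hat / w))


def convergence_report(
    samples: PosteriorSamples, threshold: float = 1.2, split: bool = False
) -> pd.DataFrame:
    """Per-parameter R-hat table with a pass/fail column.

    The overall verdict (max R-hat <= ``threshold``) is stored in
    ``frame.attrs["converged"]`` and ``frame.attrs["max_rhat"]``.
    """
    if samples.n_chains < 2:
        raise ValueError(
            "convergence diagnostics require >= 2 chains; re-run with n_chains >= 2"
        )
    rows = []
    for name in samples.names:
        r = rhat(samples, name, split=split)
        rows.append({"parameter": name, "rhat": r, "converged": r <= threshold})
    frame = pd.DataFrame(rows)
    frame.attrs["max_rhat"] = float(frame["rhat"].max())
    frame.attrs["converged"] = bool(frame["converged"].all())
    frame.attrs["threshold"] = threshold
    return frame
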
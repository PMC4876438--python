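"""Synthetic two-group connectome cohorts with known planted effects.

The generator emulates the statistical shape of a probabilistic-
tractography cohort: 90-node symmetric weighted matrices whose raw
sparsity exceeds the top of the analysis grid, with small-world
topology (gamma >> 1, lambda ~ 1 after thresholding), and a "case"
(amusic) group carrying three independent planted effects --
an increased normalized path length lambda, a decreased clustering
coefficient Cp, and an increased nodal strength at one designated
region (the right inferior parietal lobule by default) -- plus
behavioural scores whose distributions match the study cohort and
whose lexical-tone score is rank-coupled to each subject's lambda AUC.

Construction per subject
------------------------
1. Ring lattice of N nodes, each linked to its k nearest neighbours,
   k chosen from the raw-sparsity target.
2. Log-normal edge weights decaying with ring distance, so that
   thresholding at any grid sparsity keeps mostly short-range edges
   (high clustering) and the network stays connected.
3. Watts-Strogatz rewiring of a fraction beta of edges into random
   long-range shortcuts that *keep their strong weights*; these
   surviving shortcuts are what keeps lambda close to 1.
4. Case group only: a fraction ``delta_lambda`` of the shortcuts is
   relocated back to local positions (fewer strong long-range links ->
   lambda rises; edges keep their weights), and the strongest ~0.5%
   of weights are boosted by ``delta_cp`` with the subject total
   restored (rank-preserving, so thresholded topologies are
   identical; the inflated network maximum lowers the max-rescaled
   weighted clustering coefficient Cp while lambda, a ratio against
   surrogates sharing the same weights, is unaffected).
5. Case group only: all weights incident to the target node are
   multiplied by ``nodal_multiplier``.
6. Per-edge multiplicative log-normal subject noise.

Behavioural scores use the printed cohort means/SDs; the tone score is
coupled to the lambda AUC through a Gaussian copula whose latent
correlation is calibrated (by a small internal Monte-Carlo bisection)
so that the *pooled* Spearman correlation matches the configured
target despite per-group locations, scales and the [0, 100] ceiling.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

from wmnet._seeds import derive_seed
from wmnet.atlas import aal90_index, aal90_labels
from wmnet.core import (
    ConnectivityMatrix,
    check_no_isolated_nodes,
    is_connected,
    threshold_by_sparsity,
)
from wmnet.sweep import auc, compute_curves, sparsity_grid

CONTROL = "control"
AMUSIC = "amusic"

__all__ = ["CohortSpec", "CohortData", "generate_subject", "generate_behaviour",
           "generate_cohort", "resolve_target_index"]


@dataclass(frozen=True)
class CohortSpec:
    """All knobs of the synthetic cohort, with study-cohort defaults."""

    n_control: int = 24
    n_amusic: int = 31
    n_nodes: int = 90
    raw_sparsity: float = 0.35           # must exceed the top grid sparsity
    shortcut_prob: float = 0.10          # Watts-Strogatz rewiring probability
    weight_sigma: float = 0.40           # log-normal weight spread
    distance_decay: float = 4.0          # ring-distance scale of weight decay
    weight_scale: float = 0.5            # overall weight magnitude
    subject_noise: float = 0.10          # per-edge log-normal subject noise
    # planted case-group effects
    delta_lambda: float = 0.5            # fraction of shortcuts relocalized
    delta_cp: float = 0.30               # boost of the top-percentile weights
    nodal_target: str | int = "Parietal_Inf_R"
    nodal_multiplier: float = 1.5
    # behavioural score distributions (mean, SD), percent scale
    mbea_control: tuple[float, float] = (88.019, 6.029)
    mbea_amusic: tuple[float, float] = (64.063, 5.185)
    mbea_cutoff: float = 71.7
    tone_control: tuple[float, float] = (97.472, 2.891)
    tone_amusic: tuple[float, float] = (86.083, 14.695)
    tone_lambda_rho: float = -0.3        # target pooled Spearman(tone, lambda AUC)
    # demographics (mean, SD[, min, max])
    age_control: tuple[float, float, float, float] = (21.9, 1.9, 17, 25)
    age_amusic: tuple[float, float, float, float] = (21.8, 3.3, 17, 30)
    iq_control: tuple[float, float] = (125.6, 6.0)
    iq_amusic: tuple[float, float] = (123.6, 6.8)
    brain_control: tuple[float, float] = (1415.3, 110.1)
    brain_amusic: tuple[float, float] = (1421.2, 106.6)
    male_fraction_control: float = 10 / 24
    male_fraction_amusic: float = 13 / 31
    # analysis settings used when coupling behaviour to the lambda AUC
    coupling_grid: tuple[float, float, float] = (0.09, 0.27, 0.02)
    coupling_n_random: int = 16
    gate_sparsity: float = 0.09          # subjects must be valid here
    seed: int = 0

    def __post_init__(self) -> None:
        if self.raw_sparsity <= max(self.coupling_grid[1], self.gate_sparsity):
            raise ValueError("raw_sparsity must exceed the analysis grid maximum")
        if min(self.delta_lambda, self.delta_cp) < 0 or self.nodal_multiplier < 0:
            raise ValueError("effect sizes must be >= 0")
        if abs(self.tone_lambda_rho) >= 1:
            raise ValueError("infeasible rank-correlation target")
        if self.n_nodes < 6:
            raise ValueError("n_nodes too small for a ring scaffold")

    @property
    def ring_half_degree(self) -> int:
        khalf = int(round(self.raw_sparsity * (self.n_nodes - 1) / 2))
        return max(2, min(khalf, (self.n_nodes - 1) // 2))

    def node_labels(self) -> tuple[str, ...]:
        if self.n_nodes == 90:
            return aal90_labels()
        return tuple(f"node_{i + 1}" for i in range(self.n_nodes))


def resolve_target_index(spec: CohortSpec) -> int:
    """0-based index of the node carrying the planted strength effect."""
    if isinstance(spec.nodal_target, int):
        if not 0 <= spec.nodal_target < spec.n_nodes:
            raise ValueError("nodal_target index out of range")
        return spec.nodal_target
    if spec.n_nodes == 90:
        return aal90_index(spec.nodal_target)
    # non-atlas network sizes: a fixed interior position
    return (2 * spec.n_nodes) // 3


def _as_rng(rng_seed) -> np.random.Generator:
    if isinstance(rng_seed, np.random.Generator):
        return rng_seed
    return np.random.default_rng(rng_seed)


def _reroute(e: int, u: np.ndarray, v: np.ndarray, adj: np.ndarray,
             candidates, rng: np.random.Generator, tries: int = 50) -> bool:
    """Move edge e's far endpoint to a draw from ``candidates()``.

    Keeps u[e]; rejects self-loops and existing edges; gives up (edge
    unchanged) after ``tries`` rejected draws."""
    a, b = int(u[e]), int(v[e])
    for _ in range(tries):
        c = int(candidates())
        if c == a or c == b or adj[a, c]:
            continue
        adj[a, b] = adj[b, a] = False
        adj[a, c] = adj[c, a] = True
        v[e] = c
        return True
    return False


def _build_weights(spec: CohortSpec, group: str, rng: np.random.Generator) -> np.ndarray:
    n = spec.n_nodes
    khalf = spec.ring_half_degree
    offsets = np.arange(1, khalf + 1)
    base = np.arange(n)
    u = np.concatenate([base for _ in offsets])
    v = np.concatenate([(base + off) % n for off in offsets])
    d = np.concatenate([np.full(n, off) for off in offsets]).astype(float)
    m = u.size
    logw = (np.log(spec.weight_scale)
            - (d - 1) / spec.distance_decay
            + spec.weight_sigma * rng.standard_normal(m))
    adj = np.zeros((n, n), dtype=bool)
    adj[u, v] = True
    adj[v, u] = True
    shortcut = np.zeros(m, dtype=bool)
    # Watts-Strogatz shortcut rewiring; rewired edges keep their weights
    for e in np.nonzero(rng.random(m) < spec.shortcut_prob)[0]:
        if _reroute(e, u, v, adj, lambda: rng.integers(n), rng):
            shortcut[e] = True
    if group == AMUSIC:
        sc = np.nonzero(shortcut)[0]
        n_sel = int(round(spec.delta_lambda * sc.size))
        if n_sel > 0:
            def local_target(a):
                off = int(rng.integers(1, khalf + 1))
                sign = -1 if rng.random() < 0.5 else 1
                return (a + sign * off) % n
            for e in rng.choice(sc, size=n_sel, replace=False):
                a = int(u[e])
                if _reroute(e, u, v, adj, lambda: local_target(a), rng):
                    shortcut[e] = False
    logw = logw + spec.subject_noise * rng.standard_normal(m)
    if group == AMUSIC and spec.delta_cp > 0:
        # A few abnormally strong connections: boost the top ~0.5% of
        # weights by (1 + delta_cp) and restore the subject total.
        # Rank order is untouched (same retained edge sets, same
        # binary networks).  The inflated network maximum suppresses
        # every max-rescaled Onnela triangle term, lowering the
        # weighted Cp by ~1/(1 + delta_cp); lambda is unaffected
        # because the surrogates share the same weight multiset, and
        # per-node strength is essentially untouched since the boosted
        # edges fall on different (noise-selected) nodes per subject.
        total = np.exp(logw).sum()
        k_top = max(1, int(round(0.005 * m)))
        top = np.argpartition(logw, -k_top)[-k_top:]
        logw[top] += np.log1p(spec.delta_cp)
        logw = logw + np.log(total / np.exp(logw).sum())
    w = np.zeros((n, n))
    w[u, v] = np.exp(logw)
    w = w + w.T
    if group == AMUSIC and spec.nodal_multiplier != 1.0:
        # Boost the target node's incident weights, then shrink each
        # neighbour's remaining edges so the neighbours' own total
        # strength is unchanged: the planted effect stays confined to
        # the target node instead of bleeding into its (fixed) ring
        # neighbours across all subjects.
        tgt = resolve_target_index(spec)
        old_t = w[tgt, :].copy()
        gain = (spec.nodal_multiplier - 1.0) * old_t
        scale = np.ones(n)
        for j in np.nonzero(old_t)[0]:
            other = w[j, :].sum() - old_t[j]
            if other > 0:
                scale[j] = max(1.0 - gain[j] / other, 0.1)
        w *= scale[None, :]
        w *= scale[:, None]
        w[tgt, :] = old_t * spec.nodal_multiplier
        w[:, tgt] = old_t * spec.nodal_multiplier
        np.fill_diagonal(w, 0.0)
    return w


def generate_subject(spec: CohortSpec, group: str, rng_seed,
                     subject_id: str | None = None,
                     max_retries: int = 20) -> ConnectivityMatrix:
    """Draw one subject's connectivity matrix.

    The draw is repeated (continuing the same random stream) until the
    matrix passes validation with no isolated node and a single
    connected component at the gate sparsity; in practice the first
    draw almost always passes.
    """
    if group not in (CONTROL, AMUSIC):
        raise ValueError(f"unknown group {group!r}")
    rng = _as_rng(rng_seed)
    if subject_id is None:
        subject_id = f"{group}_subject"
    labels = spec.node_labels()
    for _ in range(max_retries):
        w = _build_weights(spec, group, rng)
        cm = ConnectivityMatrix(subject_id=subject_id, weights=w, node_labels=labels)
        t = threshold_by_sparsity(cm, spec.gate_sparsity)
        if check_no_isolated_nodes(t) and is_connected(t):
            return cm
    raise RuntimeError(
        f"could not generate a valid subject after {max_retries} attempts"
    )


# ---------------------------------------------------------------------------
# behaviour


def _trunc_normal(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                             random_state=rng)


@lru_cache(maxsize=64)
def _latent_rho(target: float, n_control: int, n_amusic: int,
                tone_control: tuple, tone_amusic: tuple,
                cal_seed: int = 20160523, reps: int = 400) -> float:
    """Latent Gaussian-copula correlation whose induced pooled Spearman
    (after per-group location/scale and [0, 100] clipping) equals the
    target, found by bisection on a common-random-numbers Monte-Carlo
    estimate."""
    if target == 0.0:
        return 0.0
    n = n_control + n_amusic
    mu = np.r_[np.full(n_control, tone_control[0]), np.full(n_amusic, tone_amusic[0])]
    sd = np.r_[np.full(n_control, tone_control[1]), np.full(n_amusic, tone_amusic[1])]
    rng = np.random.default_rng(cal_seed)
    # common random numbers: latent scores for the "lambda" ranks and noise
    perms = np.argsort(rng.random((reps, n)), axis=1)
    ranks = np.argsort(perms, axis=1) + 1.0
    u_all = sps.norm.ppf((ranks - 0.5) / n)
    eps = rng.standard_normal((reps, n))

    def mean_spearman(rho_p: float) -> float:
        z = rho_p * u_all + np.sqrt(1 - rho_p**2) * eps
        tone = np.clip(mu + sd * z, 0.0, 100.0)
        vals = [sps.spearmanr(tone[r], u_all[r]).statistic for r in range(reps)]
        return float(np.mean(vals))

    lo, hi = (-0.999, 0.0) if target < 0 else (0.0, 0.999)
    try:
        return float(optimize.brentq(lambda r: mean_spearman(r) - target,
                                     lo, hi, xtol=5e-3))
    except ValueError:
        # target unreachable under clipping: saturate at the extreme
        return lo if target < 0 else hi


def generate_behaviour(spec: CohortSpec, groups, lambda_auc=None, rng_seed=None,
                       subject_ids=None) -> pd.DataFrame:
    """Draw the phenotype table for a cohort.

    ``groups`` is the per-subject group label sequence; ``lambda_auc``
    the per-subject lambda AUC used for the tone-score coupling (may be
    None when the correlation target is zero).  Amusic MBEA scores are
    drawn from a normal truncated below the diagnostic cutoff.
    """
    rng = _as_rng(rng_seed)
    groups = list(groups)
    n = len(groups)
    is_case = np.array([g == AMUSIC for g in groups])
    if subject_ids is None:
        subject_ids = [f"sub{i + 1:03d}" for i in range(n)]

    def per_group(fn_control, fn_case):
        out = np.empty(n)
        out[~is_case] = fn_control(int((~is_case).sum()))
        out[is_case] = fn_case(int(is_case.sum()))
        return out

    age = per_group(
        lambda k: _trunc_normal(rng, *spec.age_control, size=k),
        lambda k: _trunc_normal(rng, *spec.age_amusic, size=k),
    )
    iq = per_group(
        lambda k: rng.normal(*spec.iq_control, size=k),
        lambda k: rng.normal(*spec.iq_amusic, size=k),
    )
    brain = per_group(
        lambda k: rng.normal(*spec.brain_control, size=k),
        lambda k: rng.normal(*spec.brain_amusic, size=k),
    )
    mbea = per_group(
        lambda k: np.clip(rng.normal(*spec.mbea_control, size=k), 0, 100),
        lambda k: _trunc_normal(rng, *spec.mbea_amusic, 0.0, spec.mbea_cutoff, size=k),
    )

    def sex_vector(k, frac):
        males = int(round(frac * k))
        vec = np.array(["M"] * males + ["F"] * (k - males))
        return vec[rng.permutation(k)]

    sex = np.empty(n, dtype=object)
    sex[~is_case] = sex_vector(int((~is_case).sum()), spec.male_fraction_control)
    sex[is_case] = sex_vector(int(is_case.sum()), spec.male_fraction_amusic)

    mu = np.where(is_case, spec.tone_amusic[0], spec.tone_control[0])
    sd = np.where(is_case, spec.tone_amusic[1], spec.tone_control[1])
    if spec.tone_lambda_rho != 0.0 and lambda_auc is not None:
        lam = np.asarray(lambda_auc, dtype=float)
        if lam.size != n:
            raise ValueError("lambda_auc length does not match cohort size")
        rho_p = _latent_rho(spec.tone_lambda_rho, int((~is_case).sum()),
                            int(is_case.sum()), tuple(spec.tone_control),
                            tuple(spec.tone_amusic))
        ranks = sps.rankdata(lam, method="average")
        u = sps.norm.ppf((ranks - 0.5) / n)
        z = rho_p * u + np.sqrt(1 - rho_p**2) * rng.standard_normal(n)
    else:
        z = rng.standard_normal(n)
    tone = np.clip(mu + sd * z, 0.0, 100.0)

    return pd.DataFrame({
        "subject_id": subject_ids,
        "group": groups,
        "mbea": mbea,
        "tone": tone,
        "age": age,
        "sex": sex,
        "iq": iq,
        "brain_size": brain,
    })


# ---------------------------------------------------------------------------
# cohort


@dataclass
class CohortData:
    matrices: list[ConnectivityMatrix]
    phenotypes: pd.DataFrame
    manifest: dict
    lambda_auc: np.ndarray | None = None


def generate_cohort(spec: CohortSpec, out_dir: str | os.PathLike | None = None,
                    couple_behaviour: bool | None = None) -> CohortData:
    """Generate a full cohort: matrices, phenotype table, manifest.

    Deterministic given ``spec.seed``: subject seeds and the behaviour
    seed are derived from it, so the same spec reproduces the cohort
    bit-identically.  When the tone-lambda correlation target is
    nonzero (and ``couple_behaviour`` is not False), each subject's
    lambda AUC is computed with the spec's coupling settings to drive
    the copula.  With ``out_dir`` set, matrices, labels, phenotypes and
    the manifest are written in the pipeline's input formats.
    """
    ids = ([f"con{i + 1:02d}" for i in range(spec.n_control)]
           + [f"amu{i + 1:02d}" for i in range(spec.n_amusic)])
    groups = [CONTROL] * spec.n_control + [AMUSIC] * spec.n_amusic
    matrices = [
        generate_subject(spec, g, derive_seed(spec.seed, "subject", sid),
                         subject_id=sid)
        for sid, g in zip(ids, groups)
    ]
    if couple_behaviour is None:
        couple_behaviour = spec.tone_lambda_rho != 0.0
    lambda_auc = None
    if couple_behaviour:
        grid = sparsity_grid(*spec.coupling_grid)
        lambda_auc = np.array([
            auc(compute_curves(m, grid, weighted=True,
                               n_random=spec.coupling_n_random,
                               seed=derive_seed(spec.seed, "coupling"),
                               include_nodal=False).global_curves["lambda"])
            for m in matrices
        ])
    pheno = generate_behaviour(spec, groups, lambda_auc,
                               rng_seed=derive_seed(spec.seed, "behaviour"),
                               subject_ids=ids)
    manifest = {
        "generator": "wmnet.simulate",
        "spec": dataclasses.asdict(spec),
        "seed": spec.seed,
        "subject_seeds": {sid: derive_seed(spec.seed, "subject", sid) for sid in ids},
        "groups": dict(zip(ids, groups)),
        "planted_effects": {
            "lambda_increase_fraction": spec.delta_lambda,
            "cp_decrease_fraction": spec.delta_cp,
            "nodal_target_index": resolve_target_index(spec),
            "nodal_target_label": spec.node_labels()[resolve_target_index(spec)],
            "nodal_multiplier": spec.nodal_multiplier,
            "tone_lambda_rho": spec.tone_lambda_rho,
        },
        "behaviour_coupled": bool(couple_behaviour),
    }
    data = CohortData(matrices=matrices, phenotypes=pheno, manifest=manifest,
                      lambda_auc=lambda_auc)
    if out_dir is not None:
        _write_cohort(data, spec, out_dir)
    return data


def _write_cohort(data: CohortData, spec: CohortSpec, out_dir) -> None:
    os.makedirs(out_dir, exist_ok=True)
    for m in data.matrices:
        np.savetxt(os.path.join(out_dir, f"{m.subject_id}.txt"), m.weights,
                   fmt="%.10g")
    with open(os.path.join(out_dir, "labels.txt"), "w") as fh:
        fh.write("\n".join(spec.node_labels()) + "\n")
    data.phenotypes.to_csv(os.path.join(out_dir, "phenotypes.tsv"), sep="\t",
                           index=False)
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(data.manifest, fh, indent=2, default=str)
        fh.write("\n")
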
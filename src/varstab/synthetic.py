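"""Synthetic inputs with known ground truth.

Every input the pipeline consumes can be emulated here: alignments drawn
from a known Potts model (exactly, for independent columns; by Gibbs
sampling otherwise) and variant tables in which stability change and
evolutionary energy jointly determine the pathogenicity label through a
stated logistic model. Effect sizes mirror the study regime: about 60% of
pathogenic variants are strongly destabilized, steady-state abundance
drops sigmoidally with a half-drop near ddG = 3 kcal/mol, and the default
logistic parameters are (w_ddg, w_evo, b) = (0.5, 3.5, -1.5).

All generators are pure functions of their spec, seed included.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

from .coevolution import ALPHABET, Q, Alignment, PottsModel
from .variants import AMINO_ACIDS, VariantRecord, VariantTable

__all__ = [
    "GeneratorSpec",
    "sample_independent_msa",
    "sample_potts_msa",
    "make_random_potts_model",
    "make_synthetic_variant_table",
]


def _states_to_alignment(X: np.ndarray, query: str) -> Alignment:
    seqs = ["".join(ALPHABET[a] for a in row) for row in X]
    return Alignment(
        sequences=[query] + seqs,
        query_index=0,
        column_map=tuple(range(1, len(query) + 1)),
        ids=["query"] + [f"seq{i}" for i in range(len(seqs))],
    )


def _consensus_query(h: np.ndarray) -> str:
    """Most favorable amino acid per column (gap excluded)."""
    return "".join(AMINO_ACIDS[int(np.argmax(row[: Q - 1]))] for row in h)


def sample_independent_msa(h: np.ndarray, n: int, seed: int) -> Alignment:
    """Exact sampling of columns from softmax(h_i), independently.

    The returned alignment carries a gap-free consensus query as row 0.
    """
    h = np.asarray(h, dtype=float)
    L, q = h.shape
    if q != Q:
        raise ValueError(f"fields must have q = {Q} states")
    rng = np.random.default_rng(seed)
    p = np.exp(h - h.max(axis=1, keepdims=True))
    p /= p.sum(axis=1, keepdims=True)
    cdf = np.cumsum(p, axis=1)
    u = rng.random((n, L))
    X = (cdf[None, :, :] < u[:, :, None]).sum(axis=2)
    return _states_to_alignment(X, _consensus_query(h))


def sample_potts_msa(
    model: PottsModel, n: int, seed: int, burn_in: int = 200, thin: int = 1
) -> Alignment:
    """Gibbs sampling: n parallel chains, ``burn_in + thin`` full sweeps each.

    The default burn-in is sized for strongly coupled models; for J = 0
    the sampler is exact after the first sweep. Chains are independent,
    so samples are uncorrelated regardless of ``thin``.
    """
    rng = np.random.default_rng(seed)
    h, J = model.h, model.J
    L, q = h.shape
    # independent-site initialization
    p0 = np.exp(h - h.max(axis=1, keepdims=True))
    p0 /= p0.sum(axis=1, keepdims=True)
    cdf0 = np.cumsum(p0, axis=1)
    X = (cdf0[None, :, :] < rng.random((n, L))[:, :, None]).sum(axis=2)
    for _ in range(burn_in + thin):
        for i in range(L):
            logits = np.broadcast_to(h[i], (n, q)).copy()
            for j in range(L):
                if j == i:
                    continue
                logits += J[i, j][:, X[:, j]].T
            logits -= logits.max(axis=1, keepdims=True)
            p = np.exp(logits)
            p /= p.sum(axis=1, keepdims=True)
            X[:, i] = (np.cumsum(p, axis=1) < rng.random(n)[:, None]).sum(axis=1)
    return _states_to_alignment(X, _consensus_query(h))


def make_random_potts_model(
    L: int,
    seed: int,
    field_std: float = 1.0,
    n_coupled_pairs: int = 40,
    coupling_std: float = 0.6,
) -> PottsModel:
    """A random generating model over the 21-state alphabet.

    Fields are iid normal over the 20 amino acids; the gap state is pushed
    far down so sampled sequences are gap-free. Couplings are placed on a
    random set of column pairs, zero elsewhere and zero for the gap state.
    """
    rng = np.random.default_rng(seed)
    h = np.zeros((L, Q))
    h[:, : Q - 1] = rng.normal(0.0, field_std, size=(L, Q - 1))
    h[:, Q - 1] = -30.0  # no gaps in generated sequences
    J = np.zeros((L, L, Q, Q))
    pairs = [(i, j) for i in range(L) for j in range(i + 1, L)]
    chosen = rng.choice(len(pairs), size=min(n_coupled_pairs, len(pairs)), replace=False)
    for idx in chosen:
        i, j = pairs[idx]
        block = np.zeros((Q, Q))
        block[: Q - 1, : Q - 1] = rng.normal(0.0, coupling_std, size=(Q - 1, Q - 1))
        J[i, j] = block
        J[j, i] = block.T
    return PottsModel(
        h=h, J=J, lambda_h=0.0, lambda_J=0.0, column_map=tuple(range(1, L + 1))
    )


@dataclass
class GeneratorSpec:
    """Parameters of the synthetic variant-table regime.

    The defaults are the study conditions: pathogenic variants are
    strongly destabilized with probability ``destabilized_fraction`` (the
    ~60% destabilization-driven fraction), benign variants are stable, and
    evolutionary energies are Beta-skewed toward intolerance for
    pathogenic variants. ``label_mode`` chooses whether the recorded
    labels are drawn from the logistic model ("probabilistic") or set by
    the generating class ("deterministic").
    """

    seed: int = 0
    n: int = 116
    class_balance: float = 0.5  # fraction of pathogenic-regime variants
    w_ddg: float = 0.5
    w_evo: float = 3.5
    intercept: float = -1.5
    label_mode: str = "probabilistic"
    destabilized_fraction: float = 0.6
    benign_ddg: tuple[float, float, float, float] = (0.3, 0.7, -2.0, 2.0)
    pathogenic_ddg: tuple[float, float, float, float] = (6.0, 3.0, 1.0, 15.0)
    pathogenic_stable_ddg: tuple[float, float, float, float] = (0.5, 0.8, -2.0, 15.0)
    benign_evo: tuple[float, float] = (2.0, 6.0)
    pathogenic_evo: tuple[float, float] = (6.0, 2.0)
    steady_state_noise: float = 8.0

    def __post_init__(self) -> None:
        if not 0.0 < self.class_balance < 1.0:
            raise ValueError("class_balance must lie in (0,1)")
        if self.label_mode not in ("probabilistic", "deterministic"):
            raise ValueError("label_mode must be probabilistic or deterministic")
        for params in (
            self.benign_ddg,
            self.pathogenic_ddg,
            self.pathogenic_stable_ddg,
        ):
            if not all(np.isfinite(params)) or params[1] < 0:
                raise ValueError(f"invalid ddG distribution parameters {params}")
        for a, b in (self.benign_evo, self.pathogenic_evo):
            if a <= 0 or b <= 0:
                raise ValueError("Beta parameters must be positive")


def _clipped_normal(rng, mean, std, lo, hi, size):
    return np.clip(rng.normal(mean, std, size=size), lo, hi)


def make_synthetic_variant_table(spec: GeneratorSpec) -> tuple[VariantTable, dict]:
    """Generate a variant table plus the truth record of all parameters.

    Steady state follows SS% = 100 * (1 - 0.9 * sigmoid(ddG - 3)) + noise,
    clipped at 0, placing the half-drop near the ~3 kcal/mol degradation
    threshold.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    is_patho = rng.random(n) < spec.class_balance

    ddg = np.empty(n)
    evo = np.empty(n)
    b_mask = ~is_patho
    ddg[b_mask] = _clipped_normal(rng, *spec.benign_ddg, size=int(b_mask.sum()))
    destab = rng.random(n) < spec.destabilized_fraction
    p_destab = is_patho & destab
    p_stable = is_patho & ~destab
    ddg[p_destab] = _clipped_normal(rng, *spec.pathogenic_ddg, size=int(p_destab.sum()))
    ddg[p_stable] = _clipped_normal(
        rng, *spec.pathogenic_stable_ddg, size=int(p_stable.sum())
    )
    evo[b_mask] = rng.beta(*spec.benign_evo, size=int(b_mask.sum()))
    evo[is_patho] = rng.beta(*spec.pathogenic_evo, size=int(is_patho.sum()))

    logit = spec.w_ddg * ddg + spec.w_evo * evo + spec.intercept
    prob = 1.0 / (1.0 + np.exp(-logit))
    if spec.label_mode == "probabilistic":
        labels = (rng.random(n) < prob).astype(int)
    else:
        labels = is_patho.astype(int)

    steady = 100.0 * (1.0 - 0.9 / (1.0 + np.exp(-(ddg - 3.0))))
    steady = np.clip(steady + rng.normal(0.0, spec.steady_state_noise, size=n), 0.0, None)

    records = []
    for i in range(n):
        wt_idx = int(rng.integers(0, 20))
        mut_idx = int((wt_idx + 1 + rng.integers(0, 19)) % 20)
        records.append(
            VariantRecord(
                position=i + 1,
                wt_aa=AMINO_ACIDS[wt_idx],
                mut_aa=AMINO_ACIDS[mut_idx],
                ddg=float(ddg[i]),
                steady_state=float(steady[i]),
                clinvar_class="likely_pathogenic" if labels[i] else "likely_benign",
                evo_energy=float(np.clip(evo[i], 1e-9, 1 - 1e-9)),
            )
        )
    truth = {
        "spec": spec,
        "labels": labels,
        "generating_class": is_patho.astype(int),
        "ddg": ddg,
        "evo": evo,
        "prob": prob,
        "w_ddg": spec.w_ddg,
        "w_evo": spec.w_evo,
        "intercept": spec.intercept,
    }
    return VariantTable(records, provenance=f"synthetic(seed={spec.seed})"), truth
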
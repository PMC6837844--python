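"""Evolutionary sequence energies from a conservation + co-variation model.

A multiple sequence alignment of the protein family is summarized by a
Potts model: per-column fields ``h_i(a)`` capture site conservation and
pairwise couplings ``J_ij(a, b)`` capture co-variation between columns.
The model is fit by L2-regularized maximum pseudolikelihood with sequence
reweighting, the standard estimator for this model family. A variant is
scored by the energy difference

    dE = E(mutant) - E(wild type),
    E(seq) = -[ sum_i h_i(a_i) + sum_{i<j} J_ij(a_i, a_j) ],

so that high dE marks substitutions that are rare or unobserved across the
family. Raw scores are rank-normalized to the open interval (0, 1).

The alphabet has q = 21 states: the 20 amino acids plus the gap symbol,
which participates in fitting but is never a substitution target.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import rankdata

from .variants import AMINO_ACIDS

__all__ = [
    "GAP",
    "ALPHABET",
    "Q",
    "Alignment",
    "PottsModel",
    "EvoEnergyMatrix",
    "read_alignment",
    "sequence_weights",
    "fit_potts",
    "sequence_energy",
    "score_variant",
    "rank_normalize",
    "coverage_mask",
    "build_evo_matrix",
    "write_model",
    "read_model",
]

GAP = "-"
ALPHABET = AMINO_ACIDS + GAP
Q = len(ALPHABET)  # 21
_CHAR_TO_IDX = {c: i for i, c in enumerate(ALPHABET)}


def encode_sequence(seq: str) -> np.ndarray:
    """Map a sequence to integer states; unknown letters count as gaps."""
    return np.array([_CHAR_TO_IDX.get(c, Q - 1) for c in seq.upper()], dtype=np.int64)


@dataclass
class Alignment:
    """Reduced alignment: equal-length rows over the 21-letter alphabet.

    Retained columns are exactly those where the query row has a residue;
    ``column_map[k]`` is the 1-based query position of column ``k``.
    """

    sequences: list[str]
    query_index: int
    column_map: tuple[int, ...]
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        L = len(self.sequences[0])
        if any(len(s) != L for s in self.sequences):
            raise ValueError("alignment rows have unequal lengths")
        if len(self.column_map) != L:
            raise ValueError("column_map length must equal alignment width")
        if any(b <= a for a, b in zip(self.column_map, self.column_map[1:])):
            raise ValueError("column_map must be strictly increasing")
        if GAP in self.sequences[self.query_index]:
            raise ValueError("query row must be gap-free after reduction")

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    @property
    def query(self) -> str:
        return self.sequences[self.query_index]

    def to_matrix(self) -> np.ndarray:
        """(n_sequences, length) integer state matrix."""
        return np.stack([encode_sequence(s) for s in self.sequences])


def _read_fasta(path: Path) -> list[tuple[str, str]]:
    entries: list[tuple[str, str]] = []
    name, chunks = None, []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    entries.append((name, "".join(chunks)))
                name, chunks = line[1:].split()[0] if line[1:] else "", []
            elif line:
                chunks.append(line)
    if name is not None:
        entries.append((name, "".join(chunks)))
    return entries


def read_alignment(path: str | Path, query_id: str) -> Alignment:
    """Read a FASTA/A2M alignment and reduce it to query match columns.

    A2M convention: lowercase letters and ``.`` are insert states and are
    dropped per sequence. After that, rows must be equal length; columns
    where the query carries a gap are removed so the query is gap-free.
    """
    entries = _read_fasta(Path(path))
    if not entries:
        raise ValueError(f"{path}: no sequences")
    # drop insert states (A2M lowercase / '.')
    matchseqs = []
    for name, seq in entries:
        matchseqs.append((name, "".join(c for c in seq if not (c.islower() or c == "."))))
    lengths = {len(s) for _, s in matchseqs}
    if len(lengths) != 1:
        raise ValueError(
            f"{path}: ragged alignment after insert removal (lengths {sorted(lengths)})"
        )
    ids = [name for name, _ in matchseqs]
    try:
        qidx = ids.index(query_id)
    except ValueError:
        raise ValueError(f"{path}: query {query_id!r} not found") from None
    qseq = matchseqs[qidx][1]
    keep = [k for k, c in enumerate(qseq) if c != GAP and c != "."]
    column_map = []
    pos = 0
    for k, c in enumerate(qseq):
        if c != GAP:
            pos += 1
            column_map.append((k, pos))
    keep_idx = [k for k, _ in column_map]
    reduced = ["".join(s[k] for k in keep_idx).upper() for _, s in matchseqs]
    return Alignment(
        sequences=reduced,
        query_index=qidx,
        column_map=tuple(p for _, p in column_map),
        ids=ids,
    )


def sequence_weights(aln: Alignment, identity_threshold: float = 0.8) -> np.ndarray:
    """Inverse-cluster-size reweighting.

    ``w_s = 1 / |{t : identity(s, t) >= threshold}|`` with the self pair
    included, so 0 < w_s <= 1 and ``n_eff = sum(w)``.
    """
    X = aln.to_matrix()
    n, L = X.shape
    counts = np.zeros(n, dtype=np.int64)
    block = max(1, int(2e7 // max(n * L, 1)))
    for start in range(0, n, block):
        sub = X[start : start + block]  # (b, L)
        ident = (sub[:, None, :] == X[None, :, :]).mean(axis=2)
        counts[start : start + block] = (ident >= identity_threshold).sum(axis=1)
    return 1.0 / counts


@dataclass
class PottsModel:
    """Fitted fields and couplings, in zero-sum gauge after fitting.

    ``J`` is stored as the full (L, L, q, q) array with the symmetry
    ``J[i, j, a, b] == J[j, i, b, a]`` and zero diagonal blocks.
    """

    h: np.ndarray  # (L, q)
    J: np.ndarray  # (L, L, q, q)
    lambda_h: float
    lambda_J: float
    seq_weights: np.ndarray | None = None
    column_map: tuple[int, ...] | None = None
    converged: bool = True
    n_iter: int = 0
    grad_norm: float = 0.0

    def __post_init__(self) -> None:
        L, q = self.h.shape
        if self.J.shape != (L, L, q, q):
            raise ValueError("J shape must be (L, L, q, q)")

    @property
    def length(self) -> int:
        return self.h.shape[0]

    @property
    def q(self) -> int:
        return self.h.shape[1]

    @property
    def n_eff(self) -> float:
        return float(np.sum(self.seq_weights)) if self.seq_weights is not None else 0.0


def _gauge_fix(h: np.ndarray, J: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Transfer J block means into the fields (zero-sum gauge).

    Leaves every energy difference between sequences unchanged.
    """
    mu = J.mean(axis=3)  # (L, L, q): row means over b
    nu = J.mean(axis=2)  # (L, L, q): column means over a
    m = J.mean(axis=(2, 3))  # (L, L)
    J_new = J - mu[:, :, :, None] - nu[:, :, None, :] + m[:, :, None, None]
    h_new = h + mu.sum(axis=1)
    h_new = h_new - h_new.mean(axis=1, keepdims=True)
    return h_new, J_new


def _symmetrize(J: np.ndarray) -> np.ndarray:
    return 0.5 * (J + J.transpose(1, 0, 3, 2))


def fit_potts(
    aln: Alignment,
    lambda_h: float = 0.01,
    lambda_J: float | None = None,
    max_iter: int = 500,
    tol: float = 1e-4,
    identity_threshold: float = 0.8,
    weights: np.ndarray | None = None,
) -> PottsModel:
    """Regularized pseudolikelihood fit.

    Minimizes

        sum_s w_s sum_i -log P(x_i^s | x_-i^s; h, J)
            + lambda_h ||h||^2 + lambda_J ||J||^2

    where the conditional is the softmax of ``h_i(a) + sum_{j!=i} J_ij(a,
    x_j^s)``. ``lambda_J`` defaults to ``0.01 * (L - 1) * (q - 1)``, the
    usual length-scaled coupling penalty. Optimization is deterministic
    (quasi-Newton from zero); non-convergence is recorded on the model,
    not raised.
    """
    X = aln.to_matrix()
    n, L = X.shape
    if n < 2 or len(set(aln.sequences)) < 2:
        raise ValueError("need at least 2 distinct sequences")
    q = Q
    if lambda_J is None:
        lambda_J = 0.01 * (L - 1) * (q - 1)
    if weights is None:
        weights = sequence_weights(aln, identity_threshold)
    w = np.asarray(weights, dtype=float)

    O = np.zeros((n, L, q))
    O[np.arange(n)[:, None], np.arange(L)[None, :], X] = 1.0
    O_flat = O.reshape(n, L * q)

    n_h = L * q

    def objective(theta: np.ndarray) -> tuple[float, np.ndarray]:
        h = theta[:n_h].reshape(L, q)
        Jfull = theta[n_h:].reshape(L, L, q, q)
        Js = _symmetrize(Jfull)
        Js[np.arange(L), np.arange(L)] = 0.0
        # logits[s, i, a] = h[i, a] + sum_{j != i} Js[i, j, a, x_j^s]
        M = Js.transpose(1, 3, 0, 2).reshape(L * q, L * q)
        logits = (O_flat @ M).reshape(n, L, q) + h[None, :, :]
        lse = logsumexp(logits, axis=2)  # (n, L)
        picked = np.take_along_axis(logits, X[:, :, None], axis=2)[:, :, 0]
        nll = float(np.sum(w * np.sum(lse - picked, axis=1)))
        f = nll + lambda_h * float(np.sum(h * h)) + lambda_J * float(np.sum(Js * Js))

        P = np.exp(logits - lse[:, :, None])
        D = (P - O) * w[:, None, None]  # (n, L, q)
        grad_h = D.sum(axis=0) + 2.0 * lambda_h * h
        C = D.reshape(n, L * q).T @ O_flat  # (Lq, Lq): C[(i,a),(j,b)]
        G = C.reshape(L, q, L, q).transpose(0, 2, 1, 3)  # (L, L, q, q)
        G[np.arange(L), np.arange(L)] = 0.0
        G = G + 2.0 * lambda_J * Js
        grad_J = 0.5 * (G + G.transpose(1, 0, 3, 2))
        return f, np.concatenate([grad_h.ravel(), grad_J.ravel()])

    theta0 = np.zeros(n_h + L * L * q * q)
    res = minimize(
        objective,
        theta0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": tol, "ftol": 1e-12, "maxcor": 10},
    )
    h = res.x[:n_h].reshape(L, q)
    Js = _symmetrize(res.x[n_h:].reshape(L, L, q, q))
    Js[np.arange(L), np.arange(L)] = 0.0
    h, Js = _gauge_fix(h, Js)
    return PottsModel(
        h=h,
        J=Js,
        lambda_h=lambda_h,
        lambda_J=lambda_J,
        seq_weights=w,
        column_map=aln.column_map,
        converged=bool(res.success),
        n_iter=int(res.nit),
        grad_norm=float(np.max(np.abs(res.jac))),
    )


def sequence_energy(model: PottsModel, seq: str | np.ndarray) -> float:
    """Negative log-score of a full sequence under the model."""
    x = encode_sequence(seq) if isinstance(seq, str) else np.asarray(seq)
    L = model.length
    if len(x) != L:
        raise ValueError(f"sequence length {len(x)} != model length {L}")
    field_term = float(model.h[np.arange(L), x].sum())
    pair = model.J[np.arange(L)[:, None], np.arange(L)[None, :], x[:, None], x[None, :]]
    pair_term = 0.5 * float(pair.sum())  # diag blocks are zero
    return -(field_term + pair_term)


def score_variant(
    model: PottsModel, wt_seq: str | np.ndarray, position: int, mut_aa: str
) -> float:
    """dE = E(mutant) - E(wild type) for a single substitution.

    ``position`` is 1-based along the model columns. Computed in O(L) from
    the fields and couplings touching the mutated column; wt -> wt returns
    exactly 0.
    """
    x = encode_sequence(wt_seq) if isinstance(wt_seq, str) else np.asarray(wt_seq)
    L = model.length
    if len(x) != L:
        raise ValueError(f"sequence length {len(x)} != model length {L}")
    if not 1 <= position <= L:
        raise ValueError(f"position {position} outside 1..{L}")
    i = position - 1
    a_wt = x[i]
    a_mut = _CHAR_TO_IDX[mut_aa]
    if a_mut == a_wt:
        return 0.0
    d_field = model.h[i, a_mut] - model.h[i, a_wt]
    others = np.arange(L) != i
    d_pair = (
        model.J[i, others, a_mut, x[others]] - model.J[i, others, a_wt, x[others]]
    ).sum()
    return float(-(d_field + d_pair))


def rank_normalize(raw_scores: Sequence[float] | np.ndarray) -> np.ndarray:
    """Map scores to (0, 1) by rank: r / (N + 1), average ranks for ties.

    NA (NaN) entries are preserved; N counts non-NA entries only. The
    output is strictly inside (0, 1) and order-preserving, and depends on
    the input only through its ordering.
    """
    arr = np.asarray(raw_scores, dtype=float)
    mask = ~np.isnan(arr)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("all scores are NA")
    out = np.full(arr.shape, np.nan)
    ranks = rankdata(arr[mask], method="average")
    out[mask] = ranks / (n + 1)
    return out


def coverage_mask(
    aln: Alignment,
    weights: np.ndarray | None = None,
    min_neff_column: float = 50.0,
    max_gap_fraction: float = 0.5,
) -> set[int]:
    """Query positions with too little homologous signal to score.

    A column is masked when its weighted non-gap effective count is below
    ``min_neff_column`` (strict) or its weighted gap fraction exceeds
    ``max_gap_fraction`` (strict). Returns 1-based query positions.
    """
    if weights is None:
        weights = sequence_weights(aln)
    w = np.asarray(weights, dtype=float)
    X = aln.to_matrix()
    nongap = X != Q - 1
    eff = (nongap * w[:, None]).sum(axis=0)
    gap_frac = ((~nongap) * w[:, None]).sum(axis=0) / w.sum()
    masked = (eff < min_neff_column) | (gap_frac > max_gap_fraction)
    return {aln.column_map[k] for k in np.nonzero(masked)[0]}


@dataclass
class EvoEnergyMatrix:
    """Raw and rank-normalized variant scores over (position, mut_aa).

    Keys are (1-based query position, mutant amino acid); NA cells are
    simply absent and are identical between ``raw`` and ``normalized``.
    """

    raw: dict[tuple[int, str], float]
    normalized: dict[tuple[int, str], float]
    wt_by_position: dict[int, str]
    masked_positions: frozenset[int] = frozenset()

    def to_long_frame(self):
        import pandas as pd

        rows = [
            {
                "position": p,
                "wt": self.wt_by_position[p],
                "mut": a,
                "evo_raw": self.raw[(p, a)],
                "evo_energy": self.normalized[(p, a)],
            }
            for (p, a) in sorted(self.raw)
        ]
        return pd.DataFrame(rows)


def build_evo_matrix(
    model: PottsModel,
    wt_seq: str,
    masked_positions: Iterable[int] = (),
) -> EvoEnergyMatrix:
    """Score all 19 substitutions at every unmasked model column.

    Rank normalization runs over all scored cells of the full matrix at
    once (one common scale), not per column.
    """
    if model.column_map is not None and len(model.column_map) != len(wt_seq):
        raise ValueError("wild-type sequence length does not match model")
    masked = frozenset(masked_positions)
    colmap = model.column_map or tuple(range(1, len(wt_seq) + 1))
    keys: list[tuple[int, str]] = []
    raws: list[float] = []
    wt_by_pos: dict[int, str] = {}
    for k, qpos in enumerate(colmap):
        wt = wt_seq[k]
        wt_by_pos[qpos] = wt
        if qpos in masked:
            continue
        for a in AMINO_ACIDS:
            if a == wt:
                continue
            keys.append((qpos, a))
            raws.append(score_variant(model, wt_seq, k + 1, a))
    if not raws:
        raise ValueError(
            "every position is masked; relax the coverage-mask thresholds "
            "or provide a deeper alignment"
        )
    norm = rank_normalize(np.array(raws))
    return EvoEnergyMatrix(
        raw=dict(zip(keys, raws)),
        normalized=dict(zip(keys, norm.tolist())),
        wt_by_position=wt_by_pos,
        masked_positions=masked,
    )


def write_model(model: PottsModel, path: str | Path) -> None:
    """Serialize a model to a diffable text format (header, h block, J block)."""
    L, q = model.length, model.q
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# potts-model v1\nL\t{L}\nq\t{q}\n")
        fh.write(f"lambda_h\t{model.lambda_h!r}\nlambda_J\t{model.lambda_J!r}\n")
        fh.write(f"converged\t{int(model.converged)}\n")
        if model.column_map is not None:
            fh.write("column_map\t" + ",".join(map(str, model.column_map)) + "\n")
        fh.write("h\n")
        for i in range(L):
            fh.write("\t".join(repr(float(v)) for v in model.h[i]) + "\n")
        fh.write("J\n")
        for i in range(L):
            for j in range(i + 1, L):
                block = model.J[i, j]
                if not np.any(block):
                    continue
                fh.write(f"pair\t{i}\t{j}\n")
                for a in range(q):
                    fh.write("\t".join(repr(float(v)) for v in block[a]) + "\n")


def read_model(path: str | Path) -> PottsModel:
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    meta: dict[str, str] = {}
    k = 1  # skip magic comment
    while lines[k] != "h":
        key, val = lines[k].split("\t", 1)
        meta[key] = val
        k += 1
    L, q = int(meta["L"]), int(meta["q"])
    k += 1
    h = np.array([[float(v) for v in lines[k + i].split("\t")] for i in range(L)])
    k += L
    assert lines[k] == "J"
    k += 1
    J = np.zeros((L, L, q, q))
    while k < len(lines) and lines[k]:
        _tag, si, sj = lines[k].split("\t")
        i, j = int(si), int(sj)
        block = np.array(
            [[float(v) for v in lines[k + 1 + a].split("\t")] for a in range(q)]
        )
        J[i, j] = block
        J[j, i] = block.T
        k += 1 + q
    colmap = (
        tuple(int(v) for v in meta["column_map"].split(","))
        if "column_map" in meta
        else None
    )
    return PottsModel(
        h=h,
        J=J,
        lambda_h=float(meta["lambda_h"]),
        lambda_J=float(meta["lambda_J"]),
        column_map=colmap,
        converged=bool(int(meta.get("converged", "1"))),
    )
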
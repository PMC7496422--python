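"""Codon-level tables shared by the Ks estimator and the sequence simulator.

Everything here is precomputed once from the standard genetic code:

* NG86 synonymous-site fractions per sense codon (stop-creating changes
  count as nonsynonymous, so synonymous + nonsynonymous sites = 3 per codon);
* path-averaged synonymous/nonsynonymous difference counts for every pair of
  sense codons (mutational paths that pass through a stop codon are excluded
  from the average; if every path is blocked, all paths are used with
  stop-involving steps scored as nonsynonymous);
* the symmetric rate matrix of the synonymous single-nucleotide substitution
  process used by the simulator, together with its eigendecomposition so
  transition matrices for arbitrary branch lengths are cheap.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import permutations

import numpy as np
from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]

BASES = "ACGT"
STOP_CODONS = frozenset(_TABLE.stop_codons)
SENSE_CODONS = tuple(sorted(_TABLE.forward_table))
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
N_SENSE = len(SENSE_CODONS)  # 61
AMINO_ACID = {c: _TABLE.forward_table[c] for c in SENSE_CODONS}


def _single_step_neighbors(codon: str):
    """All 9 codons one nucleotide change away (stops included)."""
    for pos in range(3):
        for b in BASES:
            if b != codon[pos]:
                yield codon[:pos] + b + codon[pos + 1 :]


@lru_cache(maxsize=1)
def ng86_site_counts() -> np.ndarray:
    """Synonymous sites per sense codon: (# synonymous neighbors) / 3."""
    s = np.zeros(N_SENSE)
    for i, codon in enumerate(SENSE_CODONS):
        n_syn = sum(
            1
            for nb in _single_step_neighbors(codon)
            if nb not in STOP_CODONS and AMINO_ACID[nb] == AMINO_ACID[codon]
        )
        s[i] = n_syn / 3.0
    return s


def _score_path(path) -> tuple[float, float, bool]:
    """(syn steps, nonsyn steps, passes-through-stop) for one mutation order."""
    sd = nd = 0.0
    blocked = False
    for a, b in zip(path, path[1:]):
        if a in STOP_CODONS or b in STOP_CODONS:
            blocked = True
            nd += 1.0
        elif AMINO_ACID[a] == AMINO_ACID[b]:
            sd += 1.0
        else:
            nd += 1.0
    # endpoints are sense codons; only intermediates can be stops
    return sd, nd, blocked


def _pair_diff(c1: str, c2: str) -> tuple[float, float]:
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    scored = []
    for order in permutations(diff_pos):
        path = [c1]
        cur = c1
        for pos in order:
            cur = cur[:pos] + c2[pos] + cur[pos + 1 :]
            path.append(cur)
        scored.append(_score_path(path))
    open_paths = [(sd, nd) for sd, nd, blocked in scored if not blocked]
    if not open_paths:
        open_paths = [(sd, nd) for sd, nd, _ in scored]
    sd = sum(p[0] for p in open_paths) / len(open_paths)
    nd = sum(p[1] for p in open_paths) / len(open_paths)
    return sd, nd


@lru_cache(maxsize=1)
def ng86_diff_tables() -> tuple[np.ndarray, np.ndarray]:
    """61x61 path-averaged synonymous / nonsynonymous difference counts."""
    sd = np.zeros((N_SENSE, N_SENSE))
    nd = np.zeros((N_SENSE, N_SENSE))
    for i, c1 in enumerate(SENSE_CODONS):
        for j in range(i + 1, N_SENSE):
            c2 = SENSE_CODONS[j]
            s, n = _pair_diff(c1, c2)
            sd[i, j] = sd[j, i] = s
            nd[i, j] = nd[j, i] = n
    return sd, nd


@lru_cache(maxsize=1)
def synonymous_rate_matrix() -> np.ndarray:
    """Rate 1 between synonymous single-step sense-codon neighbors.

    The chain never leaves a codon's synonymous family, so no stop codon is
    ever reachable. With this normalization the expected number of
    substitutions per synonymous site is exactly 3t for every codon, because
    the total leaving rate of a codon equals 3 x (its synonymous sites).
    """
    q = np.zeros((N_SENSE, N_SENSE))
    for i, codon in enumerate(SENSE_CODONS):
        for nb in _single_step_neighbors(codon):
            if nb not in STOP_CODONS and AMINO_ACID[nb] == AMINO_ACID[codon]:
                q[i, CODON_INDEX[nb]] = 1.0
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


@lru_cache(maxsize=1)
def _eig():
    w, v = np.linalg.eigh(synonymous_rate_matrix())
    return w, v


def synonymous_transition_matrix(t: float) -> np.ndarray:
    """P(t) = expm(Q t) for the synonymous substitution chain (t >= 0)."""
    if t < 0:
        raise ValueError("time must be non-negative")
    w, v = _eig()
    p = (v * np.exp(w * t)) @ v.T
    np.clip(p, 0.0, None, out=p)
    p /= p.sum(axis=1, keepdims=True)
    return p


def encode_codons(seq: str) -> np.ndarray:
    """Codon-index array for an ungapped coding sequence; -1 marks codons
    that are unusable for counting (gaps or ambiguity). Stop codons raise."""
    if len(seq) % 3 != 0:
        raise ValueError(f"sequence length {len(seq)} is not a multiple of 3")
    seq = seq.upper().replace("U", "T")
    out = np.empty(len(seq) // 3, dtype=np.int64)
    for k in range(0, len(seq), 3):
        codon = seq[k : k + 3]
        if codon in CODON_INDEX:
            out[k // 3] = CODON_INDEX[codon]
        elif codon in STOP_CODONS:
            raise ValueError(f"stop codon {codon} at nucleotide position {k}")
        else:
            out[k // 3] = -1
    return out


def decode_codons(idx: np.ndarray) -> str:
    return "".join(SENSE_CODONS[i] for i in idx)
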
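"""Profile-HMM posterior filtering of alignment columns.

A profile HMM is built from the alignment itself: match states are the
columns with <50% gaps; transition and emission probabilities come from
the observed paths of the aligned sequences with +1 pseudocounts.  The
forward-backward algorithm then gives, for every residue, the posterior
probability that it is emitted by the state the alignment assigns it to
(its match state, or the flanking insert state for residues in non-match
columns).  Residues below the posterior threshold are replaced by gaps;
the alignment layout is otherwise untouched.
"""

from __future__ import annotations

import numpy as np

from ..constants import AMINO_ACIDS
from .alignment import Alignment, GAP

__all__ = ["build_profile_hmm", "residue_posteriors", "hmm_posterior_mask"]

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
_NEG = -np.inf


def _lse(*vals: float) -> float:
    arr = np.array(vals)
    m = arr.max()
    if m == _NEG:
        return _NEG
    return float(m + np.log(np.exp(arr - m).sum()))


class ProfileHMM:
    """Container for log-probability parameter tables (M match states)."""

    def __init__(self, match_columns, la, le_m, le_i):
        self.match_columns = match_columns  # alignment column index of M_j
        self.M = len(match_columns)
        self.la = la      # dict of transition log-prob arrays
        self.le_m = le_m  # (M+1, 20); row 0 unused
        self.le_i = le_i  # (M+1, 20); insert states I_0..I_M


def build_profile_hmm(msa: Alignment, match_gap_frac: float = 0.5) -> ProfileHMM:
    if msa.n_seqs < 2:
        raise ValueError("need at least 2 sequences")
    ncols, nseq = msa.n_cols, msa.n_seqs
    gap_frac = np.array(
        [sum(s[j] == GAP for s in msa.sequences) / nseq for j in range(ncols)]
    )
    match_cols = [j for j in range(ncols) if gap_frac[j] < match_gap_frac]
    if not match_cols:
        raise ValueError("alignment has no match columns (<50% gaps)")
    M = len(match_cols)
    col_to_match = {c: j + 1 for j, c in enumerate(match_cols)}

    # transition counts; state rows: M_j (j=0..M, with M_0 = begin),
    # I_j (j=0..M), D_j (j=1..M); targets per level j: M_{j+1}/I_j/D_{j+1}
    # (level M: end instead of M_{M+1}/D_{M+1})
    tc = {key: np.zeros(M + 1) for key in
          ("MM", "MI", "MD", "IM", "II", "ID", "DM", "DI", "DD")}
    em = np.zeros((M + 1, 20))
    ei = np.zeros((M + 1, 20))

    for seq in msa.sequences:
        prev = ("M", 0)  # begin
        for c in range(ncols):
            sym = seq[c]
            if c in col_to_match:
                j = col_to_match[c]
                state = ("M", j) if sym != GAP else ("D", j)
                if sym != GAP:
                    em[j, _AA_INDEX[sym]] += 1
                tc[prev[0] + state[0]][prev[1]] += 1
                prev = state
            elif sym != GAP:
                # insert level = number of match columns passed so far
                j = sum(1 for mc in match_cols if mc < c)
                ei[j, _AA_INDEX[sym]] += 1
                tc[prev[0] + "I"][prev[1]] += 1
                prev = ("I", j)
        tc[prev[0] + "M"][prev[1]] += 1  # transition to end counted as *M

    la = {}
    for src in "MID":
        keys = [src + "M", src + "I", src + "D"]
        counts = np.stack([tc[k] for k in keys]) + 1.0  # +1 pseudocount
        if src == "D":
            counts[:, 0] = 0.0  # D_0 does not exist
        # level M has no D_{M+1}: drop that option there
        counts[2, M] = 0.0
        total = counts.sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            probs = np.where(total > 0, counts / total, 0.0)
            for k, p in zip(keys, probs):
                la[k] = np.where(p > 0, np.log(np.where(p > 0, p, 1.0)), _NEG)

    le_m = np.log((em + 1.0) / (em + 1.0).sum(axis=1, keepdims=True))
    le_i = np.log((ei + 1.0) / (ei + 1.0).sum(axis=1, keepdims=True))
    return ProfileHMM(match_cols, la, le_m, le_i)


def _forward_backward(hmm: ProfileHMM, x_idx: np.ndarray):
    """Log forward/backward tables over states M_j, I_j, D_j.

    Returns (fM, fI, fD, bM, bI, bD, logP); tables have shape
    (L+1, M+1); row i corresponds to having emitted i residues.
    """
    M, L = hmm.M, len(x_idx)
    la = hmm.la
    fM = np.full((L + 1, M + 1), _NEG)
    fI = np.full((L + 1, M + 1), _NEG)
    fD = np.full((L + 1, M + 1), _NEG)
    fM[0, 0] = 0.0
    for i in range(L + 1):
        if i > 0:
            for j in range(1, M + 1):
                fM[i, j] = hmm.le_m[j, x_idx[i - 1]] + _lse(
                    fM[i - 1, j - 1] + la["MM"][j - 1],
                    fI[i - 1, j - 1] + la["IM"][j - 1],
                    fD[i - 1, j - 1] + la["DM"][j - 1],
                )
            for j in range(0, M + 1):
                fI[i, j] = hmm.le_i[j, x_idx[i - 1]] + _lse(
                    fM[i - 1, j] + la["MI"][j],
                    fI[i - 1, j] + la["II"][j],
                    fD[i - 1, j] + la["DI"][j] if j >= 1 else _NEG,
                )
        for j in range(1, M + 1):
            fD[i, j] = _lse(
                fM[i, j - 1] + la["MD"][j - 1],
                fI[i, j - 1] + la["ID"][j - 1],
                fD[i, j - 1] + la["DD"][j - 1] if j >= 2 else _NEG,
            )
    logP = _lse(
        fM[L, M] + la["MM"][M], fI[L, M] + la["IM"][M], fD[L, M] + la["DM"][M]
    )

    bM = np.full((L + 1, M + 1), _NEG)
    bI = np.full((L + 1, M + 1), _NEG)
    bD = np.full((L + 1, M + 1), _NEG)
    bM[L, M], bI[L, M], bD[L, M] = la["MM"][M], la["IM"][M], la["DM"][M]
    for i in range(L, -1, -1):
        for j in range(M, 0, -1):  # D chain, decreasing j
            if i == L and j == M:
                continue
            terms = [bD[i, j + 1] + la["DD"][j]] if j < M else []
            if i < L:
                if j < M:
                    terms.append(la["DM"][j] + hmm.le_m[j + 1, x_idx[i]] + bM[i + 1, j + 1])
                terms.append(la["DI"][j] + hmm.le_i[j, x_idx[i]] + bI[i + 1, j])
            bD[i, j] = _lse(*terms) if terms else _NEG
        for j in range(M, -1, -1):
            if i == L and j == M:
                continue
            mterms = [bD[i, j + 1] + la["MD"][j]] if j < M else []
            iterms = [bD[i, j + 1] + la["ID"][j]] if j < M else []
            if i < L:
                if j < M:
                    mterms.append(la["MM"][j] + hmm.le_m[j + 1, x_idx[i]] + bM[i + 1, j + 1])
                    iterms.append(la["IM"][j] + hmm.le_m[j + 1, x_idx[i]] + bM[i + 1, j + 1])
                mterms.append(la["MI"][j] + hmm.le_i[j, x_idx[i]] + bI[i + 1, j])
                iterms.append(la["II"][j] + hmm.le_i[j, x_idx[i]] + bI[i + 1, j])
            bM[i, j] = _lse(*mterms) if mterms else _NEG
            bI[i, j] = _lse(*iterms) if iterms else _NEG
    return fM, fI, fD, bM, bI, bD, logP


def residue_posteriors(msa: Alignment, match_gap_frac: float = 0.5) -> np.ndarray:
    """Posterior probability of each residue's assigned profile state.

    Returns an (n_seqs, n_cols) array; gap positions are NaN.
    """
    hmm = build_profile_hmm(msa, match_gap_frac)
    col_to_match = {c: j + 1 for j, c in enumerate(hmm.match_columns)}
    out = np.full((msa.n_seqs, msa.n_cols), np.nan)
    for r, seq in enumerate(msa.sequences):
        x_idx = np.array([_AA_INDEX[s] for s in seq if s != GAP], dtype=int)
        if len(x_idx) == 0:
            continue
        fM, fI, fD, bM, bI, bD, logP = _forward_backward(hmm, x_idx)
        i = 0
        for c in range(msa.n_cols):
            if seq[c] == GAP:
                continue
            i += 1  # residue i (1-based among ungapped)
            if c in col_to_match:
                j = col_to_match[c]
                out[r, c] = np.exp(fM[i, j] + bM[i, j] - logP)
            else:
                j = sum(1 for mc in hmm.match_columns if mc < c)
                out[r, c] = np.exp(fI[i, j] + bI[i, j] - logP)
    return out


def hmm_posterior_mask(msa: Alignment, pp_threshold: float = 0.7) -> Alignment:
    """Replace residues whose profile posterior is below the threshold by gaps."""
    if pp_threshold <= 0:
        return Alignment(msa.ids, msa.sequences, msa.columns)
    pp = residue_posteriors(msa)
    new_seqs = []
    for r, seq in enumerate(msa.sequences):
        chars = list(seq)
        for c in range(msa.n_cols):
            if chars[c] != GAP and pp[r, c] < pp_threshold:
                chars[c] = GAP
        new_seqs.append("".join(chars))
    return Alignment(msa.ids, new_seqs, msa.columns)
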
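"""ZOOPS expectation-maximization motif discovery and PWM utilities.

The discovery model is "zero or one occurrence per sequence": each input
promoter either carries one motif instance (prior probability ``lambda``,
uniform over start positions) or is pure background.  EM alternates a
posterior decode over site positions with re-estimation of the base
probability matrix from posterior-weighted counts.  An optional palindrome
constraint symmetrizes the matrix against its reverse complement, matching
the dyad symmetry of dimer-bound activator boxes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .io import BASE_INDEX, BASES

logger = logging.getLogger("fnrscan")

DEFAULT_WIDTH = 14
DEFAULT_PSEUDOCOUNT = 0.25
DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 200
DEFAULT_RESTARTS = 10
#: background of a 65% GC genome, the compositional regime of sphingomonads
GC65_BACKGROUND = np.array([0.175, 0.325, 0.325, 0.175])


@dataclass
class PWM:
    """Column-stochastic base-probability matrix with a background model."""

    matrix: np.ndarray  # (W, 4), rows sum to 1
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    name: str = "motif"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, float)
        self.background = np.asarray(self.background, float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be (W, 4)")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM columns must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def log_odds(self) -> np.ndarray:
        """(W, 4) log2(p/bg) matrix; -inf where the PWM probability is 0."""
        with np.errstate(divide="ignore"):
            return np.log2(self.matrix) - np.log2(self.background)

    def reverse_complement(self) -> "PWM":
        # base order ACGT: complement == reversed base axis
        return PWM(self.matrix[::-1, ::-1].copy(), self.background.copy(), self.name)

    def information_content(self) -> tuple[np.ndarray, float]:
        """Bits per column against a uniform background, and the total.

        IC_j = 2 - H(column j) with H in bits; a near-deterministic column
        approaches 2 bits, a uniform column contributes 0.
        """
        p = self.matrix
        with np.errstate(divide="ignore", invalid="ignore"):
            h = -np.where(p > 0, p * np.log2(p), 0.0).sum(axis=1)
        per_col = 2.0 - h
        return per_col, float(per_col.sum())

    def relative_entropy(self) -> tuple[np.ndarray, float]:
        """KL divergence (bits) of each column from the background."""
        p = self.matrix
        with np.errstate(divide="ignore", invalid="ignore"):
            kl = np.where(p > 0, p * (np.log2(p) - np.log2(self.background)), 0.0).sum(axis=1)
        return kl, float(kl.sum())


@dataclass
class MotifSite:
    """A posterior-decoded site from discovery."""

    seq_index: int
    offset: int  # 0-based start within the sequence
    posterior: float
    matched: str


@dataclass
class MotifModel:
    """A fitted ZOOPS motif: PWM, site prior and decoded sites."""

    pwm: PWM
    lam: float
    loglik: float
    sites: list[MotifSite]
    palindromic: bool = False
    loglik_trace: list[float] = field(default_factory=list)

    @property
    def low_information(self) -> bool:
        """Weak or degenerate motif: little contrast with the background
        (relative entropy < 6 bits) or a collapsed site prior."""
        return self.pwm.relative_entropy()[1] < 6.0 or self.lam < 0.2


def consensus_string(pwm: PWM, major: float = 0.75, pair: float = 0.25) -> str:
    """Render a PWM as a degenerate consensus in the field's notation.

    Per column: an uppercase base if its frequency reaches ``major``; a
    lowercase "x/y" pair (descending frequency) if the top two bases each
    reach ``pair`` and jointly reach ``major``; otherwise N.  Runs of two
    or more N columns compress to ``N_k_`` set off by hyphens, so a dyad
    motif renders like ``TTGAc/t-N_4_-g/aTCAA``.
    """
    tokens: list[str] = []
    for col in pwm.matrix:
        order = np.argsort(-col, kind="stable")
        top, second = order[0], order[1]
        if col[top] >= major:
            tokens.append(BASES[top])
        elif col[top] >= pair and col[second] >= pair and col[top] + col[second] >= major:
            tokens.append(f"{BASES[top].lower()}/{BASES[second].lower()}")
        else:
            tokens.append("N")

    parts: list[str] = []
    i = 0
    while i < len(tokens):
        if tokens[i] == "N":
            j = i
            while j < len(tokens) and tokens[j] == "N":
                j += 1
            run = j - i
            if run >= 2:
                if parts:
                    parts.append("-")
                parts.append(f"N_{run}_")
                if j < len(tokens):
                    parts.append("-")
            else:
                parts.append("N")
            i = j
        else:
            parts.append(tokens[i])
            i += 1
    return "".join(parts)


def information_content(pwm: PWM) -> tuple[np.ndarray, float]:
    """Module-level accessor for per-column and total information (bits)."""
    return pwm.information_content()


# ---------------------------------------------------------------------------
# Sequence encoding
# ---------------------------------------------------------------------------

def encode(seq: str) -> np.ndarray:
    """Encode ACGT as 0..3; any other letter (N, masked) becomes -1."""
    table = np.full(256, -1, dtype=np.int8)
    for b, i in BASE_INDEX.items():
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)].astype(np.int64)


def _window_codes(codes: np.ndarray, width: int) -> np.ndarray:
    """(m, W) integer codes of all length-W windows of one sequence."""
    return np.lib.stride_tricks.sliding_window_view(codes, width)


# ---------------------------------------------------------------------------
# ZOOPS EM
# ---------------------------------------------------------------------------

class ZoopsMotifDiscovery(BaseEstimator):
    """ZOOPS EM motif discovery over a set of promoter sequences.

    Parameters
    ----------
    width : motif width in bp (the production setting is 14 after trying
        13-15).
    n_motifs : number of motifs to report; after each accepted motif its
        posterior-decoded sites (posterior > 0.5) are masked to N and
        discovery repeats on the masked set.
    palindromic : constrain every motif to equal its reverse complement
        (counts symmetrized in the M-step).
    restarts : number of EM restarts; a starting-point screen scores every
        candidate window by a one-step ZOOPS likelihood surrogate and the
        best ``restarts`` distinct candidates initialize EM (0.7 on the
        candidate base, 0.1 elsewhere).
    pseudocount : per-base per-column pseudocount added to expected counts.
    tol / max_iter : EM stops when the log-likelihood gain drops below
        ``tol`` or after ``max_iter`` iterations.
    background : base probabilities for the background model; estimated
        from the input sequences when None.
    random_state : seed; identical seeds give bit-identical results.

    Attributes (after ``fit``)
    --------------------------
    motifs_ : list of :class:`MotifModel`, best log-likelihood first.
    pwm_, lambda_, loglik_, sites_ : convenience views of ``motifs_[0]``.
    """

    def __init__(self, width: int = DEFAULT_WIDTH, n_motifs: int = 1,
                 palindromic: bool = False, restarts: int = DEFAULT_RESTARTS,
                 pseudocount: float = DEFAULT_PSEUDOCOUNT, tol: float = DEFAULT_TOL,
                 max_iter: int = DEFAULT_MAX_ITER, background=None,
                 init_pwm: Optional[PWM] = None, random_state: Optional[int] = 0):
        self.width = width
        self.n_motifs = n_motifs
        self.palindromic = palindromic
        self.restarts = restarts
        self.pseudocount = pseudocount
        self.tol = tol
        self.max_iter = max_iter
        self.background = background
        self.init_pwm = init_pwm
        self.random_state = random_state

    # -- public API ---------------------------------------------------------

    def fit(self, X: Sequence[str], y=None):
        seqs = [getattr(s, "sequence", s) for s in X]
        if len(seqs) < 2:
            raise ValueError("motif discovery needs at least 2 sequences")
        W = int(self.width)
        if not (1 < W):
            raise ValueError("width must be > 1")
        usable = [s for s in seqs if len(s) >= W]
        if not usable:
            raise ValueError(f"all sequences shorter than motif width {W}")

        rng = np.random.default_rng(self.random_state)
        codes = [encode(s) for s in seqs]
        bg = self._background(codes)

        motifs: list[MotifModel] = []
        work = [c.copy() for c in codes]
        for _ in range(int(self.n_motifs)):
            model = self._fit_single(work, bg, rng)
            if model is None:
                break
            motifs.append(model)
            for site in model.sites:
                if site.posterior > 0.5:
                    work[site.seq_index][site.offset : site.offset + W] = -1
        if not motifs:
            raise ValueError("no motif could be fitted (insufficient usable sequence)")
        motifs.sort(key=lambda m: -m.loglik)

        self.motifs_ = motifs
        self.pwm_ = motifs[0].pwm
        self.lambda_ = motifs[0].lam
        self.loglik_ = motifs[0].loglik
        self.sites_ = motifs[0].sites
        self.n_sequences_ = len(seqs)
        return self

    # -- internals ----------------------------------------------------------

    def _background(self, codes: list[np.ndarray]) -> np.ndarray:
        if self.background is not None:
            bg = np.asarray(self.background, float)
            return bg / bg.sum()
        counts = np.zeros(4)
        for c in codes:
            valid = c[c >= 0]
            counts += np.bincount(valid, minlength=4)
        if counts.sum() == 0:
            return np.full(4, 0.25)
        bg = (counts + 1.0) / (counts.sum() + 4.0)
        return bg / bg.sum()

    def _seed_pwms(self, codes: list[np.ndarray], bg: np.ndarray,
                   rng: np.random.Generator,
                   max_candidates: int = 6000) -> list[np.ndarray]:
        """Starting-point search: screen candidate windows, keep the best.

        Every W-long window is a candidate consensus.  Mapping a candidate
        onto a 0.7/0.1 matrix, the log likelihood-ratio of window j against
        candidate c decomposes as base_j + log(7) * matches(j, c), so all
        candidates are screened with one one-hot matrix product.  A
        candidate's score sums, over sequences, the positive part of its
        best window LLR — a one-step ZOOPS surrogate.  The ``restarts``
        best distinct candidates start full EM runs.
        """
        W = int(self.width)
        if self.init_pwm is not None:
            return [np.asarray(self.init_pwm.matrix, float)]

        win_list = []
        seq_of = []
        for si, c in enumerate(codes):
            if len(c) < W:
                continue
            wins = _window_codes(c, W)
            ok = (wins >= 0).all(axis=1)
            if ok.any():
                win_list.append(wins[ok])
                seq_of.append(np.full(int(ok.sum()), si))
        if not win_list:
            return []
        wins = np.concatenate(win_list)
        seq_of = np.concatenate(seq_of)
        n = len(wins)

        onehot = np.zeros((n, W, 4), dtype=np.float32)
        onehot[np.arange(n)[:, None], np.arange(W)[None, :], wins] = 1.0
        flat = onehot.reshape(n, W * 4)
        # window-only term of the LLR: sum_k log(0.1 / bg[base_k])
        base = np.log(0.1 / bg)[wins].sum(axis=1).astype(np.float32)
        log7 = np.float32(np.log(7.0))

        if n > max_candidates:
            cand_idx = rng.choice(n, size=max_candidates, replace=False)
            cand_idx.sort()
        else:
            cand_idx = np.arange(n)
        # windows are concatenated in sequence order: segment-max via reduceat
        seg_starts = np.flatnonzero(np.diff(seq_of, prepend=seq_of[0] - 1))
        scores = np.empty(len(cand_idx), dtype=np.float32)
        block = 256
        for b0 in range(0, len(cand_idx), block):
            idx = cand_idx[b0 : b0 + block]
            matches = flat[idx] @ flat.T  # (block, n)
            llr = base[None, :] + log7 * matches
            np.maximum(llr, 0.0, out=llr)
            # per candidate: sum over sequences of the best window LLR
            scores[b0 : b0 + block] = np.maximum.reduceat(llr, seg_starts, axis=1).sum(axis=1)

        order = np.argsort(-scores, kind="stable")
        seeds = []
        seen: set[tuple] = set()
        for oi in order:
            word = tuple(wins[cand_idx[oi]])
            if word in seen:
                continue
            seen.add(word)
            m = np.full((W, 4), 0.1)
            for j, bb in enumerate(word):
                m[j, bb] = 0.7
            seeds.append(m)
            if len(seeds) >= int(self.restarts):
                break
        return seeds

    def _fit_single(self, codes: list[np.ndarray], bg: np.ndarray,
                    rng: np.random.Generator) -> Optional[MotifModel]:
        W = int(self.width)
        windows = []
        valid = []
        for c in codes:
            if len(c) < W:
                windows.append(np.zeros((0, W), dtype=np.int64))
                valid.append(np.zeros(0, dtype=bool))
                continue
            wins = _window_codes(c, W)
            windows.append(wins)
            valid.append((wins >= 0).all(axis=1))
        if not any(v.any() for v in valid):
            return None

        best: Optional[MotifModel] = None
        for seed_matrix in self._seed_pwms(codes, bg, rng):
            model = self._em(windows, valid, seed_matrix, bg)
            if model is not None and (best is None or model.loglik > best.loglik):
                best = model
        if best is not None and best.low_information:
            logger.info("motif flagged low-information (IC=%.2f bits, lambda=%.3f)",
                        best.pwm.information_content()[1], best.lam)
        return best

    def _em(self, windows: list[np.ndarray], valid: list[np.ndarray],
            matrix: np.ndarray, bg: np.ndarray) -> Optional[MotifModel]:
        W = int(self.width)
        lam = 0.5
        alpha = float(self.pseudocount)
        matrix = matrix / matrix.sum(axis=1, keepdims=True)
        if self.palindromic:
            matrix = 0.5 * (matrix + matrix[::-1, ::-1])
        log_bg = np.log(bg)
        trace: list[float] = []
        prev_ll = -np.inf
        col_idx = np.arange(W)

        for _ in range(int(self.max_iter)):
            log_m = np.log(matrix)
            total_ll = 0.0
            gammas: list[np.ndarray] = []
            occ = []
            for wins, ok in zip(windows, valid):
                m = len(wins)
                if m == 0 or not ok.any():
                    gammas.append(np.zeros(m))
                    occ.append(0.0)
                    total_ll += np.log1p(-lam) if lam < 1 else -np.inf
                    continue
                # log likelihood-ratio of a site at each valid start
                llr = np.where(
                    ok,
                    (log_m[col_idx, wins] - log_bg[wins]).sum(axis=1),
                    -np.inf,
                )
                n_ok = int(ok.sum())
                with np.errstate(over="ignore"):
                    w = np.where(ok, lam / n_ok * np.exp(llr), 0.0)
                z = (1.0 - lam) + w.sum()
                gam = w / z
                gammas.append(gam)
                occ.append(gam.sum())
                total_ll += float(np.log(z))
            trace.append(total_ll)

            counts = np.zeros((W, 4))
            for wins, gam in zip(windows, gammas):
                if len(wins) == 0:
                    continue
                nz = gam > 0
                if not nz.any():
                    continue
                sub = wins[nz]
                g = gam[nz]
                for k in range(W):
                    np.add.at(counts[k], sub[:, k], g)
            if self.palindromic:
                counts = 0.5 * (counts + counts[::-1, ::-1])
            matrix = counts + alpha
            matrix /= matrix.sum(axis=1, keepdims=True)
            if self.palindromic:
                matrix = 0.5 * (matrix + matrix[::-1, ::-1])
            n_active = sum(1 for v in valid if v.any())
            lam = float(np.clip(sum(occ) / max(n_active, 1), 1e-6, 1 - 1e-6))

            if total_ll - prev_ll < self.tol and np.isfinite(prev_ll):
                break
            prev_ll = total_ll

        # posterior decode with the final parameters
        log_m = np.log(matrix)
        sites: list[MotifSite] = []
        final_ll = 0.0
        for i, (wins, ok) in enumerate(zip(windows, valid)):
            m = len(wins)
            if m == 0 or not ok.any():
                final_ll += np.log1p(-lam)
                continue
            llr = np.where(ok, (log_m[col_idx, wins] - log_bg[wins]).sum(axis=1), -np.inf)
            n_ok = int(ok.sum())
            with np.errstate(over="ignore"):
                w = np.where(ok, lam / n_ok * np.exp(llr), 0.0)
            z = (1.0 - lam) + w.sum()
            final_ll += float(np.log(z))
            gam = w / z
            j = int(np.argmax(gam))
            if gam[j] > 0:
                word = "".join(BASES[b] if b >= 0 else "N" for b in wins[j])
                sites.append(MotifSite(seq_index=i, offset=j, posterior=float(gam[j]),
                                       matched=word))
        trace.append(final_ll)
        pwm = PWM(matrix=matrix, background=bg.copy())
        return MotifModel(pwm=pwm, lam=lam, loglik=final_ll, sites=sites,
                          palindromic=bool(self.palindromic), loglik_trace=trace)


def discover(
    seqs: Sequence,
    width: int = DEFAULT_WIDTH,
    n_motifs: int = 5,
    palindromic: bool = False,
    restarts: int = DEFAULT_RESTARTS,
    seed: Optional[int] = 0,
    **kwargs,
) -> list[MotifModel]:
    """Run ZOOPS discovery and return fitted motifs, best first."""
    est = ZoopsMotifDiscovery(width=width, n_motifs=n_motifs, palindromic=palindromic,
                              restarts=restarts, random_state=seed, **kwargs)
    est.fit(seqs)
    return est.motifs_
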
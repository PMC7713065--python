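"""PWM scanning with exact p-values and the discover/scan/re-discover loop.

Scores are log2 likelihood ratios (bits) of a window under the motif versus
an i.i.d. background.  P-values are exact under that background model: the
per-column score distributions are discretized at a fine granularity and
convolved by dynamic programming, the standard construction of FIMO-class
scanners.  Overlapping hits within one promoter are resolved greedily to
the best p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .io import BASES
from .motifs import PWM, MotifModel, ZoopsMotifDiscovery, encode

logger = logging.getLogger("fnrscan")

DEFAULT_P_MAX = 1e-4
DEFAULT_EPSILON = 1e-3  # score discretization, bits


@dataclass
class ScanHit:
    """A thresholded PWM match within one scanned sequence."""

    seq_index: int
    ref_id: str
    offset: int  # 0-based start within the scanned sequence
    matched: str
    score: float  # log-odds, bits
    p_value: float
    strand: str = "+"


class PWMScanner(BaseEstimator):
    """Scan sequences with a PWM; exact p-values by score convolution.

    Parameters
    ----------
    pwm : the position weight matrix to scan with (its background model is
        used unless ``background`` overrides it).
    p_max : report hits with p-value at or below this threshold.
    epsilon : score discretization granularity in bits for the exact
        p-value dynamic programme.
    background : optional override of the background base probabilities.
    both_strands : also scan the reverse complement (used for genome-wide
        5' scans where orientation is per gene).

    ``fit`` precomputes the integer score matrix and the exact null score
    distribution; ``transform`` (or :meth:`scan`) returns thresholded,
    overlap-resolved hits sorted by ascending p-value.
    """

    def __init__(self, pwm: Optional[PWM] = None, p_max: float = DEFAULT_P_MAX,
                 epsilon: float = DEFAULT_EPSILON, background=None,
                 both_strands: bool = False):
        self.pwm = pwm
        self.p_max = p_max
        self.epsilon = epsilon
        self.background = background
        self.both_strands = both_strands

    # -- fitting ------------------------------------------------------------

    def fit(self, X=None, y=None):
        if self.pwm is None:
            raise ValueError("PWMScanner requires a pwm")
        bg = np.asarray(self.background if self.background is not None
                        else self.pwm.background, float)
        bg = bg / bg.sum()
        self.background_ = bg
        with np.errstate(divide="ignore"):
            self.log_odds_ = np.log2(self.pwm.matrix) - np.log2(bg)
        eps = float(self.epsilon)
        # integer per-column scores; -inf (zero PWM prob) pinned far below range
        finite = np.isfinite(self.log_odds_)
        lo = self.log_odds_.copy()
        floor = (lo[finite].min() if finite.any() else 0.0) - 100.0
        lo[~finite] = floor
        self.int_scores_ = np.rint(lo / eps).astype(np.int64)

        # DP convolution of the null distribution of the integer total score
        pmf = np.array([1.0])
        offset = 0  # value of pmf index 0
        for j in range(self.pwm.width):
            col = self.int_scores_[j]
            cmin, cmax = int(col.min()), int(col.max())
            new = np.zeros(len(pmf) + (cmax - cmin), float)
            for b in range(4):
                shift = int(col[b]) - cmin
                new[shift : shift + len(pmf)] += bg[b] * pmf
            pmf = new
            offset += cmin
        self.null_pmf_ = pmf
        self.null_offset_ = offset  # integer score of pmf index 0
        # survival function: P(total >= s)
        self.null_sf_ = np.cumsum(pmf[::-1])[::-1]
        return self

    def _check_fitted(self):
        if not hasattr(self, "null_sf_"):
            self.fit()

    # -- p-values -----------------------------------------------------------

    def score_pvalue(self, score: float) -> float:
        """Exact P(score' >= score) under the i.i.d. background model.

        ``score`` is in bits; it is mapped onto the discretized axis of the
        precomputed null distribution with a half-bin-per-column tolerance,
        so an achievable total at or above the score is never excluded by
        rounding (discretization error <= (W/2 + 1) * epsilon bits).  p is
        monotone non-increasing in the score and equals 1 at or below the
        minimum achievable score.
        """
        self._check_fitted()
        margin = self.pwm.width // 2 + 1
        s_int = int(np.rint(score / float(self.epsilon))) - margin
        return self._pvalue_int(s_int)

    def _pvalue_int(self, s_int: int) -> float:
        idx = s_int - self.null_offset_
        if idx <= 0:
            return 1.0
        if idx >= len(self.null_sf_):
            return 0.0
        return float(self.null_sf_[idx])

    # -- scanning -----------------------------------------------------------

    def transform(self, X) -> list[ScanHit]:
        return self.scan(X)

    def scan(self, X: Sequence) -> list[ScanHit]:
        """Scan sequences (strings or PromoterRegion-like) for motif hits.

        Every offset is scored on the given strand (both strands with
        ``both_strands=True``); windows containing non-ACGT letters are
        skipped and counted in the log.  Hits with p <= p_max are resolved
        greedily per sequence (best p first, no overlaps) and returned
        sorted by ascending p-value.
        """
        self._check_fitted()
        W = self.pwm.width
        hits: list[ScanHit] = []
        n_skipped = 0
        for i, item in enumerate(X):
            seq = getattr(item, "sequence", item)
            ref = getattr(item, "ref_id", f"seq{i}")
            if len(seq) < W:
                continue
            cand: list[ScanHit] = []
            fwd, n_skip = self._scan_one(seq, i, ref, "+")
            cand.extend(fwd)
            n_skipped += n_skip
            if self.both_strands:
                from Bio.Seq import Seq

                rc = str(Seq(seq).reverse_complement())
                rev, n_skip = self._scan_one(rc, i, ref, "-")
                # map offsets back onto the forward sequence
                for h in rev:
                    h.offset = len(seq) - W - h.offset
                cand.extend(rev)
                n_skipped += n_skip
            hits.extend(_resolve_overlaps(cand, W))
        if n_skipped:
            logger.info("scan: %d window(s) containing non-ACGT letters skipped", n_skipped)
        hits.sort(key=lambda h: (h.p_value, h.ref_id, h.offset))
        return hits

    def _scan_one(self, seq: str, index: int, ref: str, strand: str):
        W = self.pwm.width
        codes = encode(seq)
        wins = np.lib.stride_tricks.sliding_window_view(codes, W)
        ok = (wins >= 0).all(axis=1)
        n_skipped = int((~ok).sum())
        if not ok.any():
            return [], n_skipped
        col = np.arange(W)
        ints = np.where(ok, self.int_scores_[col, np.where(wins >= 0, wins, 0)].sum(axis=1),
                        np.iinfo(np.int64).min)
        scores = np.where(ok, np.where(wins >= 0, self.log_odds_[col, np.where(wins >= 0, wins, 0)], 0.0).sum(axis=1), -np.inf)
        out = []
        for j in np.flatnonzero(ok):
            p = self._pvalue_int(int(ints[j]))
            if p <= self.p_max:
                word = seq[j : j + W]
                out.append(ScanHit(seq_index=index, ref_id=ref, offset=int(j),
                                   matched=word, score=float(scores[j]), p_value=p,
                                   strand=strand))
        return out, n_skipped

    def window_pvalues(self, seq: str) -> np.ndarray:
        """Exact p-value of every window (NaN where the window is invalid)."""
        self._check_fitted()
        W = self.pwm.width
        codes = encode(seq)
        if len(codes) < W:
            return np.zeros(0)
        wins = np.lib.stride_tricks.sliding_window_view(codes, W)
        ok = (wins >= 0).all(axis=1)
        col = np.arange(W)
        safe = np.where(wins >= 0, wins, 0)
        ints = self.int_scores_[col, safe].sum(axis=1)
        idx = ints - self.null_offset_
        pv = np.where(idx <= 0, 1.0,
                      np.where(idx >= len(self.null_sf_), 0.0,
                               self.null_sf_[np.clip(idx, 0, len(self.null_sf_) - 1)]))
        return np.where(ok, pv, np.nan)

    def window_scores(self, seq: str) -> np.ndarray:
        """Continuous log-odds score of every window (NaN where invalid)."""
        self._check_fitted()
        W = self.pwm.width
        codes = encode(seq)
        if len(codes) < W:
            return np.zeros(0)
        wins = np.lib.stride_tricks.sliding_window_view(codes, W)
        ok = (wins >= 0).all(axis=1)
        col = np.arange(W)
        safe = np.where(wins >= 0, wins, 0)
        scores = self.log_odds_[col, safe].sum(axis=1)
        return np.where(ok, scores, np.nan)


def _resolve_overlaps(cand: list[ScanHit], width: int) -> list[ScanHit]:
    """Greedy best-p-first selection of non-overlapping hits in one sequence."""
    accepted: list[ScanHit] = []
    for h in sorted(cand, key=lambda h: (h.p_value, -h.score, h.offset)):
        if all(abs(h.offset - a.offset) >= width for a in accepted):
            accepted.append(h)
    return accepted


def scan(pwm: PWM, seqs: Sequence, p_max: float = DEFAULT_P_MAX,
         both_strands: bool = False, background=None) -> list[ScanHit]:
    """Scan sequences with a PWM (functional wrapper over PWMScanner)."""
    return PWMScanner(pwm=pwm, p_max=p_max, both_strands=both_strands,
                      background=background).fit().scan(seqs)


def score_pvalue(pwm: PWM, score: float, epsilon: float = DEFAULT_EPSILON,
                 background=None) -> float:
    """Exact p-value of a log-odds score under the background model."""
    return PWMScanner(pwm=pwm, epsilon=epsilon, background=background).fit().score_pvalue(score)


# ---------------------------------------------------------------------------
# Refinement loop
# ---------------------------------------------------------------------------

@dataclass
class RefinedMotifReport:
    """Output of the discover -> scan -> re-discover refinement."""

    initial: MotifModel
    refined: MotifModel
    hit_positive: list[str]  # ref_ids of promoters with a hit in step 2
    target_hits: dict[str, list[ScanHit]]
    refined_from_initial: bool = True


def refine(
    seed_promoters: Sequence,
    all_promoters: Sequence,
    width: int = 14,
    palindromic: bool = False,
    p_max: float = DEFAULT_P_MAX,
    restarts: int = 10,
    seed: Optional[int] = 0,
    target_sets: Optional[dict[str, Sequence]] = None,
    initial_motif: Optional[MotifModel] = None,
    discovery_kwargs: Optional[dict] = None,
) -> RefinedMotifReport:
    """Motif refinement: discover on a seed set, rescan, re-discover.

    1. ZOOPS discovery on ``seed_promoters`` (skipped when
       ``initial_motif`` is supplied);
    2. scan ``all_promoters`` with the motif at ``p_max``;
    3. re-discover on the hit-positive subset, seeding EM from the step-1
       matrix, giving the refined motif;
    4. scan any ``target_sets`` with the refined motif.

    If step 2 yields no hit-positive promoters the initial motif is
    reported unrefined, with a warning.
    """
    kwargs = dict(discovery_kwargs or {})
    if initial_motif is None:
        disc = ZoopsMotifDiscovery(width=width, n_motifs=1, palindromic=palindromic,
                                   restarts=restarts, random_state=seed, **kwargs)
        disc.fit(seed_promoters)
        initial = disc.motifs_[0]
    else:
        initial = initial_motif

    hits = scan(initial.pwm, all_promoters, p_max=p_max)
    positive_ids = sorted({h.ref_id for h in hits})
    by_id = {getattr(p, "ref_id", f"seq{i}"): p for i, p in enumerate(all_promoters)}
    positive = [by_id[r] for r in positive_ids if r in by_id]

    if len(positive) >= 2:
        redisc = ZoopsMotifDiscovery(width=initial.pwm.width, n_motifs=1,
                                     palindromic=palindromic, restarts=restarts,
                                     init_pwm=initial.pwm, random_state=seed, **kwargs)
        redisc.fit(positive)
        refined = redisc.motifs_[0]
        refined_flag = True
    else:
        logger.warning("refine: %d hit-positive promoter(s); reporting initial motif unrefined",
                       len(positive))
        refined = initial
        refined_flag = False

    target_hits: dict[str, list[ScanHit]] = {}
    for name, seqs in (target_sets or {}).items():
        target_hits[name] = scan(refined.pwm, seqs, p_max=p_max)

    return RefinedMotifReport(initial=initial, refined=refined,
                              hit_positive=positive_ids, target_hits=target_hits,
                              refined_from_initial=refined_flag)
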
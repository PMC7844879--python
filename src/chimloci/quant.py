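"""EM quantification of common read loci.

Each read segment s either maps to a CRL c (y_{s,c} = 1) or not; the
committed origin z_{s,c} is hidden whenever a segment maps to several
CRLs.  With rho_c = Pr[s from c] the observed-data likelihood is

    L(rho) = prod_s sum_c y_{s,c} rho_c ,

whose maximizer has no closed form; it is found by EM:

    E-step:  E[z_{s,c}] = rho_c / sum_{c'} y_{s,c'} rho_{c'}   (y_{s,c}=1)
    M-step:  rho_c <- sum_s E[z_{s,c}] / N

iterated until sum_c |rho_c^(t+1) - rho_c^(t)| <= epsilon.  log L is
concave in rho, so EM converges to the global maximum.  A chimeric read
contributes one row per segment; a segment multi-mapping only within one
CRL is an effectively unique row.  Abundances are reported in TPM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class MappingMatrices:
    """Uncommitted mapping indicator Y and (after EM) the posterior
    E[z_{s,c}] over read segments x CRLs.

    Both are stored row-sparse: ``rows[i]`` holds the column indices of
    the nonzero entries of segment ``segments[i]``; ``posterior[i]``
    holds the matching posterior values.
    """

    segments: List[str]
    crls: List[str]
    rows: List[np.ndarray]
    posterior: List[np.ndarray] = field(default_factory=list)

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def n_crls(self) -> int:
        return len(self.crls)

    def posterior_of(self, segment_id: str) -> Dict[str, float]:
        i = self.segments.index(segment_id)
        return {self.crls[c]: float(p)
                for c, p in zip(self.rows[i], self.posterior[i])}


@dataclass
class AbundanceVector:
    rho: np.ndarray
    n_iterations: int
    converged: bool
    epsilon: float = 1e-5
    #: log L(rho^(t)) after each M-step (non-decreasing)
    loglik_trace: List[float] = field(default_factory=list)
    #: sum_c |rho^(t+1) - rho^(t)| at the final iteration
    last_delta: float = float("nan")


def build_y(read_segments: Sequence, crls: Sequence) -> MappingMatrices:
    """Build the indicator Y from read segments and CRL membership.

    y_{s,c} = 1 iff some candidate locus of segment s belongs to CRL c;
    several candidate loci inside one CRL still contribute a single 1
    (the segment is uniquely mapped at CRL resolution).
    """
    locus_to_crl: Dict[str, int] = {}
    crl_ids = [c.crl_id for c in crls]
    for idx, crl in enumerate(crls):
        for locus_id in crl.member_loci:
            locus_to_crl[locus_id] = idx
    seg_ids: List[str] = []
    rows: List[np.ndarray] = []
    for seg in read_segments:
        cols = {locus_to_crl[l] for l in seg.candidates if l in locus_to_crl}
        missing = [l for l in seg.candidates if l not in locus_to_crl]
        if missing:
            raise ValueError(
                f"segment {seg.segment_id}: candidate loci {missing} belong to no CRL")
        if not cols:
            raise ValueError(f"segment {seg.segment_id} has no CRL-resolvable candidate")
        seg_ids.append(seg.segment_id)
        rows.append(np.array(sorted(cols), dtype=np.intp))
    return MappingMatrices(segments=seg_ids, crls=crl_ids, rows=rows)


def log_likelihood(m: MappingMatrices, rho: np.ndarray) -> float:
    """log L(rho) = sum_s log(sum_{c: y_{s,c}=1} rho_c)."""
    with np.errstate(divide="ignore"):
        return float(sum(np.log(rho[row].sum()) for row in m.rows))


def em_quantify(m: MappingMatrices, epsilon: float = 1e-5, max_iter: int = 1000,
                ) -> Tuple[AbundanceVector, MappingMatrices]:
    """Run the EM iteration to the stated stopping rule.

    Starts from the uniform rho = 1/K.  Returns the abundance vector and
    the matrices with the final E-step posterior attached.  Convergence to
    a simplex boundary is allowed; no smoothing is applied.
    """
    n, k = m.n_segments, m.n_crls
    if n == 0:
        raise ValueError("no read segments to quantify")
    rho = np.full(k, 1.0 / k)
    converged = False
    it = 0
    delta = float("nan")
    trace: List[float] = []
    # flatten the row-sparse structure once for vectorized E/M steps
    flat_cols = np.concatenate(m.rows) if m.rows else np.empty(0, dtype=np.intp)
    row_id = np.repeat(np.arange(n), [len(r) for r in m.rows])
    for it in range(1, max_iter + 1):
        vals = rho[flat_cols]
        denom = np.bincount(row_id, weights=vals, minlength=n)
        post = vals / denom[row_id]
        new_rho = np.bincount(flat_cols, weights=post, minlength=k) / n
        delta = np.abs(new_rho - rho).sum()
        rho = new_rho
        trace.append(log_likelihood(m, rho))
        if delta <= epsilon:
            converged = True
            break
    if not converged:
        logger.warning("EM did not converge in %d iterations (last delta sum > %g)",
                       max_iter, epsilon)
    # final E-step posterior from the converged abundances
    vals = rho[flat_cols]
    denom = np.bincount(row_id, weights=vals, minlength=n)
    with np.errstate(invalid="ignore"):
        post = vals / denom[row_id]
    # a segment whose every candidate CRL has rho 0 (possible only before
    # convergence) falls back to a uniform row
    offsets = np.cumsum([0] + [len(r) for r in m.rows])
    posterior = []
    for i in range(n):
        row = post[offsets[i]:offsets[i + 1]]
        if not np.isfinite(row).all():
            row = np.full(len(row), 1.0 / len(row))
        posterior.append(row)
    m.posterior = posterior
    return AbundanceVector(rho=rho, n_iterations=it, converged=converged,
                           epsilon=epsilon, loglik_trace=trace,
                           last_delta=float(delta)), m


def score_pairs(posterior1: Dict[str, float], posterior2: Dict[str, float]
                ) -> Dict[Tuple[str, str], float]:
    """Pr[(s, s') in c<->c'] for every CRL pair of a chimeric read: the
    product of the two arms' posteriors.  Sums to 1 over all pairs."""
    return {(c1, c2): p1 * p2
            for c1, p1 in posterior1.items()
            for c2, p2 in posterior2.items()}


def tpm(abundances: AbundanceVector) -> np.ndarray:
    """Transcripts per million: rho * 1e6.

    The CRLs are short captured interaction sites of comparable length,
    so length normalization is omitted and relative abundance scales
    directly to TPM.
    """
    return abundances.rho * 1e6
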
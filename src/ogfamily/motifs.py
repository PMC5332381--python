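"""Orthogroup-specific motif discovery in N-terminal regions (ZOOPS EM).

The conserved C-terminal domain dominates naive motif searches, so motifs
are sought in the hypervariable N-terminal region, extracted either from an
explicit per-record domain start or from the first conserved block of an
anchor alignment. The motif model is ZOOPS (zero or one occurrence per
sequence): with prior probability gamma a sequence carries one site at a
uniform position, otherwise it is pure background. Parameters are fitted by
expectation-maximisation with restarts seeded from the highest-scoring
words of the data; significance is assessed against an empirical null of
shuffled sequences fitted with the identical protocol.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.special import logsumexp

from .datamodel import AMINO_ACIDS, DataError, ProteinRecord
from .blocks_phylo import MSA, BlockParams, BlockSelection

log = logging.getLogger("ogfamily")

#: stricter block profile for locating the conserved-domain start: the
#: relaxed phylogeny defaults admit sporadic N-terminal columns, which would
#: drag the anchor into the hypervariable region
ANCHOR_BLOCK_PARAMS = BlockParams(
    min_conserved_frac=0.7,
    min_flank_frac=0.85,
    max_nonconserved_run=4,
    min_block_length=10,
)

_IDX = {c: i for i, c in enumerate(AMINO_ACIDS + "X")}
_N_AA = 20


@dataclass
class MotifModel:
    width: int
    pwm: np.ndarray  # (width, 20), rows sum to 1
    background: np.ndarray  # (20,)
    gamma: float  # site prior
    #: per-sequence site: id -> (1-based start, log-odds score) or None
    sites: dict[str, Optional[tuple[int, float]]] = field(default_factory=dict)
    information_content: float = 0.0
    score: float = 0.0  # ZOOPS log-likelihood-ratio objective
    null_mean: float = 0.0
    null_sd: float = 0.0

    @property
    def consensus(self) -> str:
        return "".join(AMINO_ACIDS[int(k)] for k in self.pwm.argmax(axis=1))

    def log_odds(self) -> np.ndarray:
        """(width, 21) log-odds matrix; X scores 0."""
        lo = np.zeros((self.width, _N_AA + 1))
        lo[:, :_N_AA] = np.log(self.pwm) - np.log(self.background)[None, :]
        return lo


@dataclass
class MotifReport:
    og_id: str
    motifs: list[MotifModel]
    exceptions: list[str]
    nterm_source: str = "domain_start"  # or "msa-anchor"


# ---------------------------------------------------------------------------
# N-terminal extraction
# ---------------------------------------------------------------------------

def estimate_domain_starts(msa: MSA, selection: BlockSelection) -> dict[str, int]:
    """Map the first conserved-block column to a 1-based residue position
    per sequence (gaps before the column do not count)."""
    if not selection.kept_columns:
        raise DataError("empty block selection")
    c0 = selection.kept_columns[0]
    out: dict[str, int] = {}
    for sid, row in zip(msa.ids, msa.rows):
        out[sid] = sum(1 for ch in row[:c0] if ch != "-") + 1
    return out


def extract_nterm(
    record: ProteinRecord,
    anchor: Optional[tuple[MSA, BlockSelection]] = None,
) -> str:
    """Residues strictly before the conserved-domain start.

    Precedence: the record's explicit ``domain_start``, then the estimate
    from the anchor alignment's first conserved block.
    """
    if record.domain_start is not None:
        start = record.domain_start
    elif anchor is not None:
        msa, selection = anchor
        starts = estimate_domain_starts(msa, selection)
        if record.id not in starts:
            raise DataError(f"{record.id!r} not in anchor alignment")
        start = starts[record.id]
    else:
        raise DataError(f"{record.id}: neither domain_start nor anchor available")
    nterm = record.sequence[: start - 1]
    if not nterm:
        log.warning("extract_nterm: %s has an empty N-terminal region", record.id)
    return nterm


# ---------------------------------------------------------------------------
# ZOOPS EM
# ---------------------------------------------------------------------------

def _normalise_input(seqs) -> tuple[list[str], list[str]]:
    if not seqs:
        raise DataError("no sequences")
    if isinstance(seqs[0], (tuple, list)):
        ids = [s[0] for s in seqs]
        seq_strs = [s[1] for s in seqs]
    else:
        ids = [f"seq{i}" for i in range(len(seqs))]
        seq_strs = list(seqs)
    return ids, [s.upper() for s in seq_strs]


class _Windows:
    """All width-w windows of all sequences, flattened for vectorised EM."""

    def __init__(self, encoded: list[np.ndarray], width: int):
        self.width = width
        self.n_seqs = len(encoded)
        windows = []
        seg_starts = []
        self.m = np.zeros(self.n_seqs, dtype=np.int64)
        pos = 0
        for s, e in enumerate(encoded):
            k = len(e) - width + 1
            if k < 1:
                continue
            w = np.lib.stride_tricks.sliding_window_view(e, width)
            windows.append(w)
            seg_starts.append(pos)
            self.m[s] = k
            pos += k
        if not windows:
            raise DataError(f"all sequences shorter than width {width}")
        self.P = np.concatenate(windows, axis=0)  # (T, width)
        self.has_windows = np.flatnonzero(self.m)
        self.starts = np.array(seg_starts, dtype=np.int64)
        self._krange = np.arange(width)

    def llr(self, log_odds: np.ndarray) -> np.ndarray:
        return log_odds[self._krange, self.P].sum(axis=1)

    def seg_logsumexp(self, x: np.ndarray) -> np.ndarray:
        mx = np.maximum.reduceat(x, self.starts)
        rep = np.repeat(mx, self.m[self.has_windows])
        sums = np.add.reduceat(np.exp(x - rep), self.starts)
        return mx + np.log(sums)


def _background(encoded: list[np.ndarray], pseudocount: float = 1.0) -> np.ndarray:
    counts = np.full(_N_AA, pseudocount)
    for e in encoded:
        c = np.bincount(e[e < _N_AA], minlength=_N_AA)
        counts += c
    return counts / counts.sum()


def _em_fit(
    win: _Windows,
    pwm0: np.ndarray,
    background: np.ndarray,
    gamma0: float,
    pseudocount: float,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, float, float]:
    """Run ZOOPS EM from one start; returns (pwm, gamma, objective).

    The objective (log-likelihood ratio against the background-only model)
    is asserted non-decreasing at every iteration.
    """
    pwm = pwm0.copy()
    gamma = gamma0
    obj = -np.inf
    prev_pen = -np.inf
    log_bg = np.log(background)
    n_seqs = win.n_seqs
    m_act = win.m[win.has_windows].astype(float)
    for _ in range(max_iter):
        lo = np.zeros((win.width, _N_AA + 1))
        lo[:, :_N_AA] = np.log(pwm) - log_bg[None, :]
        llr = win.llr(lo)
        lse = win.seg_logsumexp(llr)
        log_site = np.log(gamma) - np.log(m_act) + lse
        log_nosite = np.log1p(-gamma)
        denom = np.logaddexp(log_nosite, log_site)
        obj = float(denom.sum())
        # with pseudocounts the M-step is a Dirichlet-MAP update, so the
        # monotone quantity is the penalised objective
        pen = obj + pseudocount * float(np.log(pwm).sum())
        assert pen >= prev_pen - 1e-6, "EM objective decreased"
        if pen - prev_pen < tol:
            break
        prev_pen = pen
        # E-step: per-window posteriors
        z = np.exp(
            np.log(gamma)
            - np.log(np.repeat(m_act, win.m[win.has_windows]))
            + llr
            - np.repeat(denom, win.m[win.has_windows])
        )
        # M-step
        counts = np.full((win.width, _N_AA), pseudocount)
        for k in range(win.width):
            col = win.P[:, k]
            ok = col < _N_AA
            np.add.at(counts[k], col[ok], z[ok])
        pwm = counts / counts.sum(axis=1, keepdims=True)
        site_post = np.exp(log_site - denom)
        gamma = float(np.clip(site_post.sum() / n_seqs, 1e-4, 1 - 1e-4))
    return pwm, gamma, obj


def _seed_pwms(win: _Windows, background: np.ndarray, n_seeds: int) -> list[np.ndarray]:
    """Top-scoring distinct words, scored by total best-window match count."""
    P = win.P
    uniq, first = np.unique(P, axis=0, return_index=True)
    # drop words containing X
    keep = (uniq < _N_AA).all(axis=1)
    uniq, first = uniq[keep], first[keep]
    scores = []
    for row in uniq:
        matches = (P == row[None, :]).sum(axis=1)
        best_per_seq = np.maximum.reduceat(matches, win.starts)
        scores.append(best_per_seq.sum())
    order = sorted(range(len(uniq)), key=lambda i: (-scores[i], int(first[i])))
    pwms = []
    for i in order[:n_seeds]:
        pwm = np.tile(background * 0.5, (win.width, 1))
        pwm[np.arange(win.width), uniq[i]] += 0.5
        pwm /= pwm.sum(axis=1, keepdims=True)
        pwms.append(pwm)
    return pwms


def _fit_width(encoded, ids, width, background, gamma0, pseudocount,
               n_seeds, max_iter, tol):
    win = _Windows(encoded, width)
    best = None
    for pwm0 in _seed_pwms(win, background, n_seeds):
        pwm, gamma, obj = _em_fit(win, pwm0, background, gamma0, pseudocount,
                                  max_iter, tol)
        if best is None or obj > best[2] + 1e-9:
            best = (pwm, gamma, obj)
    if best is None:
        return None
    pwm, gamma, obj = best
    model = MotifModel(width=width, pwm=pwm, background=background, gamma=gamma,
                       score=obj)
    model.information_content = float(
        (pwm * (np.log2(pwm) - np.log2(background)[None, :])).sum()
    )
    # final site calls
    lo = model.log_odds()
    llr = win.llr(lo)
    lse = win.seg_logsumexp(llr)
    m_act = win.m[win.has_windows].astype(float)
    log_site = np.log(gamma) - np.log(m_act) + lse
    denom = np.logaddexp(np.log1p(-gamma), log_site)
    site_post = np.exp(log_site - denom)
    sites: dict[str, Optional[tuple[int, float]]] = {i: None for i in ids}
    offset = 0
    for which, s in enumerate(win.has_windows):
        k = win.m[s]
        if site_post[which] > 0.5:
            local = llr[offset:offset + k]
            p = int(np.argmax(local))
            sites[ids[s]] = (p + 1, float(local[p]))
        offset += k
    model.sites = sites
    return model


def find_motifs(
    seqs: Sequence[Union[str, tuple]],
    wmin: int = 10,
    wmax: int = 20,
    n_motifs: int = 1,
    seed: int = 0,
    gamma0: float = 0.8,
    pseudocount: float = 0.01,
    n_seeds: int = 10,
    max_iter: int = 50,
    tol: float = 1e-4,
    n_shuffles: int = 100,
    n_select_shuffles: int = 20,
    sig_sd: float = 5.0,
) -> list[MotifModel]:
    """Discover up to ``n_motifs`` significant ZOOPS motifs.

    For each width in [wmin, wmax] EM runs from the top ``n_seeds``
    enumerated words. Because the raw objective grows with width, widths
    compete on a null-standardised score: (objective - null mean) / null sd
    over ``n_select_shuffles`` shuffled refits at the same width. The best
    width becomes the candidate, which is kept only if its objective
    exceeds mean + ``sig_sd`` standard deviations of a ``n_shuffles``-sized
    null at that width (identical fitting protocol on independently
    shuffled sequences). Accepted sites are masked with X and the search
    repeats. Deterministic for fixed inputs and seed.
    """
    if wmin > wmax:
        raise DataError("wmin must be <= wmax")
    ids, seq_strs = _normalise_input(list(seqs))
    if len(seq_strs) < 2:
        raise DataError("need at least 2 sequences")
    if all(len(s) < wmin for s in seq_strs):
        raise DataError(f"all sequences shorter than wmin={wmin}")
    rng = np.random.default_rng(seed)
    current = [s for s in seq_strs]
    accepted: list[MotifModel] = []
    for _ in range(n_motifs):
        encoded = [np.array([_IDX[c] for c in s], dtype=np.int64) for s in current]
        background = _background(encoded)
        candidate, best_z = None, -np.inf
        for width in range(wmin, wmax + 1):
            if all(len(e) < width for e in encoded):
                continue
            model = _fit_width(encoded, ids, width, background, gamma0,
                               pseudocount, n_seeds, max_iter, tol)
            if model is None:
                continue
            null = []
            for _ in range(n_select_shuffles):
                shuffled = [rng.permutation(e) for e in encoded]
                nm = _fit_width(shuffled, ids, width, background, gamma0,
                                pseudocount, n_seeds, max_iter, tol)
                null.append(nm.score if nm is not None else 0.0)
            null = np.array(null)
            z = (model.score - null.mean()) / max(null.std(ddof=1), 1e-9)
            if z > best_z + 1e-12:
                candidate, best_z = model, z
        if candidate is None:
            break
        # empirical null at the candidate width, identical protocol
        null_scores = []
        for _ in range(n_shuffles):
            shuffled = [rng.permutation(e) for e in encoded]
            m = _fit_width(shuffled, ids, candidate.width, background, gamma0,
                           pseudocount, n_seeds, max_iter, tol)
            null_scores.append(m.score if m is not None else 0.0)
        null_scores = np.array(null_scores)
        candidate.null_mean = float(null_scores.mean())
        candidate.null_sd = float(null_scores.std(ddof=1))
        threshold = candidate.null_mean + sig_sd * max(candidate.null_sd, 1e-9)
        if candidate.score <= threshold:
            break
        accepted.append(candidate)
        # mask accepted sites and continue
        masked = []
        for sid, s in zip(ids, current):
            site = candidate.sites.get(sid)
            if site is not None:
                p = site[0] - 1
                s = s[:p] + "X" * candidate.width + s[p + candidate.width:]
            masked.append(s)
        current = masked
    return accepted


def motif_exceptions(
    model: MotifModel,
    seqs: Sequence[tuple],
    threshold: float,
) -> list[str]:
    """Ids whose best site log-odds score falls below ``threshold``."""
    out = []
    lo = model.log_odds()
    for sid, s in seqs:
        e = np.array([_IDX[c] for c in s.upper()], dtype=np.int64)
        if len(e) < model.width:
            out.append(sid)
            continue
        w = np.lib.stride_tricks.sliding_window_view(e, model.width)
        scores = lo[np.arange(model.width), w].sum(axis=1)
        if float(scores.max()) < threshold:
            out.append(sid)
    return out


def motif_report(
    og_id: str,
    records: Sequence[ProteinRecord],
    anchor: Optional[tuple[MSA, BlockSelection]] = None,
    exception_threshold: float = 0.0,
    **kwargs,
) -> MotifReport:
    """Per-orthogroup motif scan of N-terminal regions."""
    source = "domain_start" if all(r.domain_start is not None for r in records) else "msa-anchor"
    pairs = [(r.id, extract_nterm(r, anchor)) for r in records]
    pairs = [(i, s) for i, s in pairs if s]
    if len(pairs) < 2:
        return MotifReport(og_id=og_id, motifs=[], exceptions=[], nterm_source=source)
    wmin = kwargs.pop("wmin", 10)
    usable = [p for p in pairs if len(p[1]) >= wmin]
    models = find_motifs(usable, wmin=wmin, **kwargs) if len(usable) >= 2 else []
    exceptions: list[str] = []
    if models:
        exceptions = motif_exceptions(models[0], pairs, exception_threshold)
    return MotifReport(og_id=og_id, motifs=models, exceptions=exceptions,
                       nterm_source=source)


def write_meme(models: Sequence[MotifModel], path, names: Optional[Sequence[str]] = None) -> None:
    """Export motifs in MEME minimal motif text format."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= %s\n\n" % AMINO_ACIDS)
        fh.write("strands: +\n\n")
        if models:
            bg = models[0].background
            fh.write("Background letter frequencies\n")
            fh.write(" ".join(f"{a} {f:.5f}" for a, f in zip(AMINO_ACIDS, bg)) + "\n\n")
        for k, m in enumerate(models):
            name = names[k] if names else m.consensus
            nsites = sum(1 for v in m.sites.values() if v is not None)
            fh.write(f"MOTIF {name}\n")
            fh.write(
                f"letter-probability matrix: alength= {_N_AA} w= {m.width} "
                f"nsites= {nsites} E= 0\n"
            )
            for row in m.pwm:
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")
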
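"""Forward search: Gibbs-sampling motif discovery against a Markov background.

A seeded ZOOPS (zero-or-one occurrence per sequence) Gibbs sampler over a
region set, scoring candidate sites by the likelihood ratio of a position
frequency model over an order-k Markov background trained on the region kind.
Found motifs' sites are masked before searching for the next motif, so
successive motifs describe distinct signals; a consensus extractor reduces a
position frequency grid to an IUPAC degenerate pattern that can feed straight
back into the pattern catalog of the reverse search.

The sampler is deliberately simple: site prior 0.5 per sequence, both strands
sampled, pseudocounts proportional to background base frequencies, fixed
iteration budget with the best-scoring configuration retained.  It is seeded
and fully deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._iupac import BASES, code_for_bases
from .patterns import MotifPattern, find_occurrences
from ._iupac import reverse_complement

_ENC = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """A/C/G/T -> 0..3; anything else (incl. N) -> -1."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


class MarkovBackground:
    """Order-k Markov model of base composition (k in 0..3).

    Conditional probabilities are maximum-likelihood frequencies with a +1
    pseudocount per cell; every context's four probabilities sum to 1 and are
    strictly positive.
    """

    def __init__(self, order: int, cond: np.ndarray, marginal: np.ndarray, trained_on: str = ""):
        self.order = order
        self.cond = cond  # shape (4**order, 4), rows sum to 1
        self.marginal = marginal  # shape (4,), overall base frequencies
        self.trained_on = trained_on
        self._log_cond = np.log(cond)
        self._log_marginal = np.log(marginal)

    @classmethod
    def train(cls, sequences, order: int = 1, trained_on: str = "") -> "MarkovBackground":
        if not 0 <= order <= 3:
            raise ValueError("background order must be in 0..3")
        if hasattr(sequences, "sequences"):  # RegionSet
            sequences = sequences.sequences.values()
        encoded = [encode(s) for s in sequences]
        total = sum(len(e) for e in encoded)
        if total < 100 * 4**order:
            raise ValueError(
                f"only {total} bp of training sequence; order {order} needs at least "
                f"{100 * 4 ** order} bp — lower the order"
            )
        n_ctx = 4**order
        counts = np.ones((n_ctx, 4), dtype=float)  # +1 pseudocount per cell
        base_counts = np.ones(4, dtype=float)
        powers = 4 ** np.arange(order - 1, -1, -1) if order else np.array([], dtype=np.int64)
        for e in encoded:
            valid = e >= 0
            base_counts += np.bincount(e[valid], minlength=4)
            if order == 0:
                continue
            if len(e) <= order:
                continue
            # context index for each position i >= order; invalid if any base in
            # the window (context or emitted base) is N
            ctx = np.zeros(len(e) - order, dtype=np.int64)
            ok = valid[order:].copy()
            for j in range(order):
                ctx += powers[j] * np.maximum(e[j : len(e) - order + j], 0)
                ok &= valid[j : len(e) - order + j]
            emitted = e[order:]
            np.add.at(counts, (ctx[ok], emitted[ok]), 1.0)
        if order == 0:
            counts = base_counts[None, :].copy()
        cond = counts / counts.sum(axis=1, keepdims=True)
        marginal = base_counts / base_counts.sum()
        return cls(order, cond, marginal, trained_on)

    def position_logprobs(self, encoded: np.ndarray) -> np.ndarray:
        """log p(base_i | preceding k bases) per position; NaN at N positions.

        Positions with fewer than k preceding bases, or with an N anywhere in
        their context, fall back to the marginal distribution.
        """
        n = len(encoded)
        lp = np.full(n, np.nan)
        valid = encoded >= 0
        lp[valid] = self._log_marginal[encoded[valid]]
        k = self.order
        if k == 0 or n <= k:
            return lp
        powers = 4 ** np.arange(k - 1, -1, -1)
        ctx = np.zeros(n - k, dtype=np.int64)
        ok = valid[k:].copy()
        for j in range(k):
            ctx += powers[j] * np.maximum(encoded[j : n - k + j], 0)
            ok &= valid[j : n - k + j]
        idx = np.nonzero(ok)[0]
        lp[idx + k] = self._log_cond[ctx[idx], encoded[idx + k]]
        return lp

    def window_logprobs(self, encoded: np.ndarray, width: int) -> np.ndarray:
        """Background log-probability of every width-window; NaN where invalid."""
        lp = self.position_logprobs(encoded)
        n = len(encoded) - width + 1
        if n <= 0:
            return np.empty(0)
        c = np.concatenate([[0.0], np.nancumsum(lp)])
        out = c[width:] - c[:-width]
        has_nan = np.isnan(lp)
        bad = np.convolve(has_nan.astype(int), np.ones(width, dtype=int), "valid") > 0
        out[bad] = np.nan
        return out


@dataclass
class MotifModel:
    """A discovered motif: frequency grid, sites, and likelihood-ratio score."""

    width: int
    pfm: np.ndarray  # (width, 4), rows sum to 1
    sites: list[tuple[str, int, str]]  # (sequence id, offset, strand)
    score: float  # log-likelihood ratio vs background over the site set
    information_content: float  # bits

    def consensus(self, min_freq: float = 0.25) -> str:
        return pwm_consensus(self.pfm, min_freq)

    def format_block(self) -> str:
        """Minimal plain-text motif block: consensus, score, grid, sites."""
        lines = [
            f"MOTIF {self.consensus()} width={self.width} "
            f"score={self.score:.3f} ic={self.information_content:.2f} "
            f"nsites={len(self.sites)}",
            "pos\t" + "\t".join(BASES),
        ]
        for j in range(self.width):
            lines.append(f"{j + 1}\t" + "\t".join(f"{v:.3f}" for v in self.pfm[j]))
        for sid, off, strand in self.sites:
            lines.append(f"site\t{sid}\t{off}\t{strand}")
        return "\n".join(lines)


def pwm_consensus(pfm: np.ndarray, min_freq: float = 0.25) -> str:
    """Smallest IUPAC code per column covering all bases with freq >= min_freq.

    A column where no base reaches ``min_freq`` degrades to the single most
    frequent base.
    """
    out = []
    for row in np.asarray(pfm):
        bases = frozenset(b for b, f in zip(BASES, row) if f >= min_freq)
        if not bases:
            bases = frozenset(BASES[int(np.argmax(row))])
        out.append(code_for_bases(bases))
    return "".join(out)


def site_set_score(
    sites: list[tuple[str, int, str]],
    sequences: dict[str, str],
    background: MarkovBackground,
    width: int,
    pseudo_weight: float = 1.0,
) -> tuple[float, np.ndarray]:
    """Log-likelihood-ratio score of a fixed site set and its frequency grid.

    The grid is the site base counts plus ``pseudo_weight`` pseudocounts split
    by background marginal frequencies; the score sums, over sites, the log
    ratio of the grid probability to the Markov-background probability of the
    site's window (reverse-strand sites are scored on their reverse
    complement).
    """
    counts = np.zeros((width, 4))
    windows = []
    for sid, off, strand in sites:
        e = encode(sequences[sid][off : off + width])
        if strand == "-":
            e = 3 - e[::-1]
        counts[np.arange(width), e] += 1.0
        windows.append((sid, off, e))
    pfm = (counts + pseudo_weight * background.marginal[None, :]) / (
        len(sites) + pseudo_weight
    )
    log_pfm = np.log(pfm)
    score = 0.0
    for sid, off, e in windows:
        bg = background.window_logprobs(encode(sequences[sid]), width)[off]
        score += float(log_pfm[np.arange(width), e].sum() - bg)
    return score, pfm


class _SeqState:
    """Per-sequence precomputation for the sampler."""

    __slots__ = (
        "sid", "enc", "bg", "valid", "valid_mask", "n_pos", "n_options",
        "chunks", "chunk_codes",
    )

    def __init__(self, sid: str, seq: str, background: MarkovBackground, width: int):
        self.sid = sid
        self.enc = encode(seq)
        self.bg = background.window_logprobs(self.enc, width)
        self.valid = np.nonzero(~np.isnan(self.bg))[0] if self.bg.size else np.empty(0, int)
        self.valid_mask = np.zeros(max(self.bg.size, 1), dtype=bool)
        self.valid_mask[self.valid] = True
        self.n_pos = len(self.valid)
        self.n_options = 2 * self.n_pos
        # windows are scored via packed base codes: rows are split into chunks
        # of <=4 positions, each chunk's bases packed into one integer, so a
        # window score is a few 256-entry table lookups instead of w gathers
        self.chunks = _chunk_layout(width)
        self.chunk_codes = []
        if self.n_pos:
            for start, size in self.chunks:
                code = np.zeros(self.n_pos, dtype=np.intp)
                for slot in range(size):
                    code = code * 4 + self.enc[self.valid + start + slot]
                self.chunk_codes.append(code)


def _chunk_layout(width: int) -> list[tuple[int, int]]:
    return [(s, min(4, width - s)) for s in range(0, width, 4)]


# slot-base decode tables for packed chunk codes, per chunk size
_DECODE: dict[int, list[np.ndarray]] = {}
for _size in (1, 2, 3, 4):
    _codes = np.arange(4**_size)
    _DECODE[_size] = [(_codes // 4 ** (_size - 1 - _slot)) % 4 for _slot in range(_size)]


def _chunk_tables(log_pfm: np.ndarray, chunks) -> list[np.ndarray]:
    """Per chunk, the score of every packed code under the grid rows."""
    tables = []
    for start, size in chunks:
        t = log_pfm[start].take(_DECODE[size][0])
        for slot in range(1, size):
            t = t + log_pfm[start + slot].take(_DECODE[size][slot])
        tables.append(t)
    return tables


def _window_scores(state: "_SeqState", log_pfm: np.ndarray, width: int) -> np.ndarray:
    """Motif log-prob of every valid window: forward then reverse strand."""
    fwd_tables = _chunk_tables(log_pfm, state.chunks)
    rc_tables = _chunk_tables(np.ascontiguousarray(log_pfm[::-1, ::-1]), state.chunks)
    fwd = fwd_tables[0].take(state.chunk_codes[0])
    for t, c in zip(fwd_tables[1:], state.chunk_codes[1:]):
        fwd += t.take(c)
    # a reverse-strand site at window i scores the window's rc: with the grid
    # itself rc'ed the same packed codes apply
    rev = rc_tables[0].take(state.chunk_codes[0])
    for t, c in zip(rc_tables[1:], state.chunk_codes[1:]):
        rev += t.take(c)
    return np.concatenate([fwd, rev])


def gibbs_motif_search(
    sequences,
    background: MarkovBackground,
    width: int = 8,
    n_motifs: int = 1,
    iterations: int = 200,
    restarts: int = 10,
    seed: int = 0,
    site_prior: float = 0.5,
    both_strands: bool = True,
) -> list[MotifModel]:
    """ZOOPS Gibbs sampling for over-represented motifs in a sequence set.

    Parameters
    ----------
    sequences : RegionSet or dict of id -> sequence
    background : MarkovBackground trained on the matching region kind
    width : motif width in nt (the analysis range is 8-25)
    n_motifs : how many motifs to report; each motif's sites are masked to N
        before the next search ("motif ranking" behaviour)
    iterations, restarts : sampler budget per motif
    seed : every restart derives its generator from this seed — the search is
        deterministic given the seed

    Returns motifs ranked by log-likelihood-ratio score; motifs that do not
    beat the background (score <= 0) are not reported.
    """
    if hasattr(sequences, "sequences"):
        sequences = dict(sequences.sequences)
    else:
        sequences = dict(sequences)
    if len(sequences) < 10:
        raise ValueError("motif discovery needs at least 10 sequences")
    if not 8 <= width <= 25:
        raise ValueError("motif width must be within 8..25")
    shortest = min(len(s) for s in sequences.values())
    if width > shortest:
        raise ValueError(f"width {width} exceeds the shortest sequence ({shortest} bp)")

    work = dict(sequences)
    found: list[MotifModel] = []
    for motif_index in range(n_motifs):
        best = _sample_one_motif(
            work, background, width, iterations, restarts, seed + 7919 * motif_index,
            site_prior, both_strands,
        )
        if best is None or best.score <= 0 or not best.sites:
            if not found:
                warnings.warn("no motif scored above the background model", stacklevel=2)
            break
        found.append(best)
        # mask found sites before the next motif
        for sid, off, _ in best.sites:
            s = work[sid]
            work[sid] = s[:off] + "N" * width + s[off + width :]
    return found


def _sample_one_motif(
    sequences: dict[str, str],
    background: MarkovBackground,
    width: int,
    iterations: int,
    restarts: int,
    seed: int,
    site_prior: float,
    both_strands: bool,
) -> MotifModel | None:
    states = [_SeqState(sid, s, background, width) for sid, s in sequences.items()]
    usable = [st for st in states if st.n_pos > 0]
    if not usable:
        return None

    best_sites: list[tuple[str, int, str]] | None = None
    best_score = -np.inf
    for restart in range(restarts):
        rng = np.random.default_rng([seed, restart])
        sites, score = _run_chain(
            usable, background, width, iterations, rng, site_prior, both_strands
        )
        if score > best_score:
            best_score, best_sites = score, sites
    if not best_sites:
        return None
    score, pfm = site_set_score(best_sites, sequences, background, width)
    ic = float(np.sum(pfm * np.log2(np.maximum(pfm, 1e-12))) + 2.0 * width)
    return MotifModel(width=width, pfm=pfm, sites=sorted(best_sites), score=score,
                      information_content=ic)


def _run_chain(states, background, width, iterations, rng, site_prior, both_strands):
    n_seq = len(states)
    marginal = background.marginal
    counts = np.zeros((width, 4))
    assign: list[tuple[int, str] | None] = [None] * n_seq

    def add_site(i, pos, strand, sign):
        e = states[i].enc[pos : pos + width]
        if strand == "-":
            e = 3 - e[::-1]
        counts[np.arange(width), e] += sign

    # random initialisation: each sequence gets a site with probability prior
    for i, st in enumerate(states):
        if rng.random() < site_prior:
            pos = int(st.valid[rng.integers(st.n_pos)])
            strand = "-" if (both_strands and rng.random() < 0.5) else "+"
            assign[i] = (pos, strand)
            add_site(i, pos, strand, +1.0)

    n_sites = sum(a is not None for a in assign)
    best_sites: list[tuple[str, int, str]] = []
    best_score = -np.inf
    order = np.arange(n_seq)
    for it in range(iterations):
        rng.shuffle(order)
        for i in order:
            st = states[i]
            if assign[i] is not None:
                pos, strand = assign[i]
                add_site(i, pos, strand, -1.0)
                n_sites -= 1
                assign[i] = None
            pfm = (counts + marginal[None, :]) / (n_sites + 1.0)
            log_pfm = np.log(pfm)
            llr = _window_scores(st, log_pfm, width)
            bgv = st.bg[st.valid]
            llr[: st.n_pos] -= bgv
            llr[st.n_pos :] -= bgv
            if not both_strands:
                llr = llr[: st.n_pos]
            n_opt = len(llr)
            # ZOOPS: P(site at option) ∝ (prior / n_opt) * LR, P(no site) ∝ 1 - prior
            m = llr.max()
            w_opts = (site_prior / n_opt) * np.exp(llr - m)
            w_none = (1.0 - site_prior) * np.exp(-m)
            total = w_opts.sum() + w_none
            u = rng.random() * total
            if u < w_none:
                continue
            idx = int(np.searchsorted(np.cumsum(w_opts), u - w_none))
            idx = min(idx, n_opt - 1)
            if idx < len(st.valid):
                pos, strand = int(st.valid[idx]), "+"
            else:
                pos, strand = int(st.valid[idx - len(st.valid)]), "-"
            assign[i] = (pos, strand)
            add_site(i, pos, strand, +1.0)
            n_sites += 1
        # every few sweeps: try phase-shift moves (the sampler can lock onto a
        # register one base off the true motif) and track the best configuration
        if n_sites and (it % 5 == 4 or it == iterations - 1):
            score = _config_score(states, assign, marginal, width)
            for delta in (-1, 1):
                shifted = [
                    (a[0] + delta, a[1])
                    if a is not None
                    and 0 <= a[0] + delta < len(states[i].valid_mask)
                    and states[i].valid_mask[a[0] + delta]
                    else None
                    for i, a in enumerate(assign)
                ]
                s_score = _config_score(states, shifted, marginal, width)
                if s_score > score:
                    assign = shifted
                    score = s_score
                    counts[:] = 0.0
                    n_sites = 0
                    for i, a in enumerate(assign):
                        if a is not None:
                            add_site(i, a[0], a[1], +1.0)
                            n_sites += 1
            if score > best_score:
                best_score = score
                best_sites = [
                    (states[i].sid, a[0], a[1]) for i, a in enumerate(assign) if a
                ]
    return best_sites, best_score


def _config_score(states, assign, marginal, width) -> float:
    """Joint log-likelihood-ratio of a site configuration under its own grid."""
    counts = np.zeros((width, 4))
    windows = []
    for i, a in enumerate(assign):
        if a is None:
            continue
        pos, strand = a
        e = states[i].enc[pos : pos + width]
        if strand == "-":
            e = 3 - e[::-1]
        counts[np.arange(width), e] += 1.0
        windows.append((i, pos, e))
    if not windows:
        return -np.inf
    log_pfm = np.log((counts + marginal[None, :]) / (len(windows) + 1.0))
    score = 0.0
    for i, pos, e in windows:
        score += float(log_pfm[np.arange(width), e].sum() - states[i].bg[pos])
    return score


def find_coexisting_motifs(
    regions,
    anchor: MotifPattern,
    background: MarkovBackground,
    mask_anchor: bool = True,
    **search_kwargs,
) -> list[MotifModel]:
    """Discover motifs co-existing with an anchor CRE in its carrier sequences.

    ``regions`` should already be restricted to anchor-bearing genes; the
    background model must be trained on ALL sequences of the region kind (not
    the carrier subset), so shared composition does not masquerade as signal.
    Anchor occurrences (both strands) are masked to N before the search unless
    ``mask_anchor=False``.
    """
    if hasattr(regions, "sequences"):
        seqs = dict(regions.sequences)
    else:
        seqs = dict(regions)
    if not seqs:
        raise ValueError("anchor-bearing sequence set is empty")
    if mask_anchor:
        w = anchor.width
        rc = reverse_complement(anchor.iupac)
        masked = {}
        for sid, s in seqs.items():
            chars = list(s)
            hits = find_occurrences(s, anchor.iupac)
            if not anchor.is_palindromic:
                hits += find_occurrences(s, rc)
            for off in hits:
                chars[off : off + w] = "N" * w
            masked[sid] = "".join(chars)
        seqs = masked
    return gibbs_motif_search(seqs, background, **search_kwargs)
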
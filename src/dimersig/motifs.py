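"""Spaced-motif enrichment and inverted-repeat scanning over peak sequences.

The central analysis asks whether a secondary DNA-binding motif occurs at a
fixed spacing from a primary motif more often than chance across a set of
ChIP-seq peak sequences — the signature of a protein dimer contacting two
half-sites.  Matches are binned by gap length and by one of four quadrants
(upstream/downstream of the primary, same/opposite strand), and each
(gap, quadrant) cell is tested with a binomial tail against a uniform null,
Bonferroni-corrected over the tested cells.

An exact-string scanner for inverted repeats of a half-site (e.g. AACAAT
separated from ATTGTT by g bases) complements the PWM machinery: it is how
candidate dimer elements such as IR1/IR5/IR10 are located and counted.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from dimersig.io import FormatError, SequenceRecord

_BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")

QUADRANTS = (
    "upstream-same",
    "upstream-opposite",
    "downstream-same",
    "downstream-opposite",
)


def revcomp(seq: str) -> str:
    """Reverse-complement a DNA string, preserving case."""
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(sequence: str) -> np.ndarray:
    """Map a sequence to integer codes; masked (lowercase/N) bases become -1.

    Only uppercase ACGT are scoreable; any window touching a masked base is
    disqualified from PWM matching.
    """
    codes = np.full(len(sequence), -1, dtype=np.int8)
    for base, code in _CODE.items():
        codes[np.frombuffer(sequence.encode(), dtype=np.uint8) == ord(base)] = code
    return codes


class PWM:
    """Position weight matrix over {A,C,G,T} with a background model.

    Parameters
    ----------
    matrix : array-like, shape (length, 4)
        Per-position probabilities; each row must sum to 1.
    background : array-like of 4 floats, optional
        Background nucleotide frequencies (default uniform); must be > 0 so
        log-odds scores are well defined.
    name : str
    pseudocount : float
        Added to probabilities before taking log-odds, avoiding -inf scores.
    """

    def __init__(self, matrix, background=None, name: str = "motif",
                 pseudocount: float = 1e-4):
        self.matrix = np.asarray(matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must have shape (length, 4)")
        sums = self.matrix.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            bad = int(np.argmax(np.abs(sums - 1.0)))
            raise ValueError(
                f"PWM {name!r}: column {bad} probabilities sum to {sums[bad]:.6f}, not 1"
            )
        self.background = (
            np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
        )
        if self.background.shape != (4,) or np.any(self.background <= 0):
            raise ValueError("background must be 4 positive frequencies")
        self.background = self.background / self.background.sum()
        self.name = name
        self.pseudocount = float(pseudocount)

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def __repr__(self) -> str:
        return f"PWM(name={self.name!r}, length={len(self)})"

    @classmethod
    def from_consensus(cls, consensus: str, name: str | None = None,
                       p_consensus: float = 0.85, background=None) -> "PWM":
        """Build a PWM from a consensus string.

        Each consensus base gets probability ``p_consensus``; the remainder is
        split over the other three bases.  ``N`` yields a uniform column.
        """
        rows = []
        for base in consensus.upper():
            if base == "N":
                rows.append(np.full(4, 0.25))
            elif base in _CODE:
                row = np.full(4, (1.0 - p_consensus) / 3.0)
                row[_CODE[base]] = p_consensus
                rows.append(row)
            else:
                raise ValueError(f"unsupported consensus character {base!r}")
        return cls(np.array(rows), background=background, name=name or consensus)

    @classmethod
    def from_counts(cls, counts, name: str = "motif", pseudocount: float = 0.1,
                    background=None) -> "PWM":
        counts = np.asarray(counts, dtype=float) + pseudocount
        return cls(counts / counts.sum(axis=1, keepdims=True),
                   background=background, name=name)

    @property
    def log_odds(self) -> np.ndarray:
        """Per-position log2 odds (matrix + pseudocount vs background), in bits."""
        p = self.matrix + self.pseudocount
        p = p / p.sum(axis=1, keepdims=True)
        return np.log2(p / self.background)

    @property
    def information_content(self) -> np.ndarray:
        """Per-column information content 2 + sum(p log2 p) bits (uniform bg)."""
        p = self.matrix + 1e-12
        return 2.0 + np.sum(self.matrix * np.log2(p), axis=1)

    def consensus(self) -> str:
        return "".join(_BASES[i] for i in np.argmax(self.matrix, axis=1))

    def reverse_complement(self) -> "PWM":
        return PWM(self.matrix[::-1, ::-1], background=self.background,
                   name=self.name, pseudocount=self.pseudocount)


@dataclass(frozen=True)
class MotifMatch:
    """Best PWM hit in a sequence: 0-based start, strand and score in bits."""

    sequence_id: str
    start: int
    strand: str
    score: float
    motif: str


def _window_scores(codes: np.ndarray, log_odds: np.ndarray) -> np.ndarray:
    """Score every window of len(log_odds); masked windows get -inf."""
    w = log_odds.shape[0]
    n = codes.size - w + 1
    if n <= 0:
        return np.empty(0)
    scores = np.zeros(n)
    masked = np.zeros(n, dtype=bool)
    for j in range(w):
        col = codes[j:j + n]
        bad = col < 0
        masked |= bad
        scores += np.where(bad, 0.0, log_odds[j][np.clip(col, 0, 3)])
    scores[masked] = -np.inf
    return scores


def best_match(seq: SequenceRecord, pwm: PWM, minscore: float = 5.0,
               _cache: dict | None = None) -> MotifMatch | None:
    """Highest-scoring PWM window over both strands, or None below threshold.

    Ties are broken by lower start, then by the + strand.  Windows containing
    masked (lowercase/N) bases are disqualified.
    """
    scores = _all_scores(seq, pwm, _cache)
    if scores is None:
        return None
    plus, minus = scores
    best = None  # (score, start, strand_rank)
    for strand_rank, (strand, arr) in enumerate((("+", plus), ("-", minus))):
        if arr.size == 0:
            continue
        i = int(np.argmax(arr))
        cand = (float(arr[i]), i, strand_rank)
        if best is None or cand[0] > best[0] or (
            cand[0] == best[0] and (cand[1], cand[2]) < (best[1], best[2])
        ):
            best = cand
    if best is None or best[0] < minscore or not math.isfinite(best[0]):
        return None
    return MotifMatch(seq.id, best[1], "+-"[best[2]], best[0], pwm.name)


def _all_scores(seq: SequenceRecord, pwm: PWM, cache: dict | None = None):
    """(plus, minus) score arrays for every window; cached per (seq, pwm)."""
    key = (id(seq), id(pwm))
    if cache is not None and key in cache:
        return cache[key]
    codes = _encode(seq.sequence)
    if codes.size < len(pwm):
        return None
    plus = _window_scores(codes, pwm.log_odds)
    minus = _window_scores(codes, pwm.reverse_complement().log_odds)
    out = (plus, minus)
    if cache is not None:
        cache[key] = out
    return out


def trim_motif(pwm: PWM, bits: float = 1.0) -> PWM:
    """Strip flanking low-information columns (IC < ``bits``); idempotent.

    Interior columns are never removed.  Raises if nothing would remain.
    """
    ic = pwm.information_content
    keep = np.flatnonzero(ic >= bits)
    if keep.size == 0:
        raise ValueError(f"all columns of {pwm.name!r} fall below {bits} bits")
    lo, hi = int(keep[0]), int(keep[-1]) + 1
    if lo == 0 and hi == len(pwm):
        return pwm
    trimmed = PWM(pwm.matrix[lo:hi], background=pwm.background,
                  name=pwm.name, pseudocount=pwm.pseudocount)
    trimmed.trim_offset = lo  # type: ignore[attr-defined]
    return trimmed


# ---------------------------------------------------------------------------
# MEME motif text format (version 4)

def read_meme_motif(path: str | Path) -> list[PWM]:
    """Parse a MEME motif text file (version 4 / minimal format)."""
    text = Path(path).read_text()
    lines = [ln.rstrip() for ln in text.splitlines()]
    background = None
    motifs: list[PWM] = []
    i = 0
    while i < len(lines):
        ln = lines[i].strip()
        if ln.startswith("ALPHABET"):
            alpha = ln.split("=", 1)[-1].strip()
            if alpha.upper() != "ACGT":
                raise FormatError(f"unsupported alphabet {alpha!r} (expected ACGT)")
        elif ln.startswith("Background letter frequencies"):
            i += 1
            toks = lines[i].split()
            freqs = {toks[j]: float(toks[j + 1]) for j in range(0, len(toks), 2)}
            background = np.array([freqs.get(b, 0.25) for b in _BASES])
        elif ln.startswith("MOTIF"):
            name = ln.split()[1]
            i += 1
            while i < len(lines) and "letter-probability matrix" not in lines[i]:
                i += 1
            if i >= len(lines):
                raise FormatError(f"motif {name!r}: missing letter-probability matrix")
            header = lines[i]
            m = re.search(r"w=\s*(\d+)", header)
            width = int(m.group(1)) if m else None
            rows = []
            i += 1
            while i < len(lines):
                toks = lines[i].split()
                if len(toks) != 4:
                    break
                try:
                    rows.append([float(t) for t in toks])
                except ValueError:
                    break
                i += 1
            i -= 1
            if width is not None and len(rows) != width:
                raise FormatError(
                    f"motif {name!r}: declared w={width} but {len(rows)} rows found"
                )
            mat = np.array(rows)
            sums = mat.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-3):
                bad = int(np.argmax(np.abs(sums - 1.0)))
                raise FormatError(
                    f"motif {name!r}: column {bad} sums to {sums[bad]:.4f}, not 1"
                )
            mat = mat / sums[:, None]
            motifs.append(PWM(mat, background=background, name=name))
        i += 1
    if not motifs:
        raise FormatError(f"no motifs found in {path}")
    return motifs


def write_meme_motif(pwms: Iterable[PWM], path: str | Path) -> None:
    """Write motifs in MEME version-4 text format (round-trips with the reader)."""
    pwms = list(pwms)
    bg = pwms[0].background if pwms else np.full(4, 0.25)
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {f:.6f}" for b, f in zip(_BASES, bg)) + "\n\n")
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.name}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {len(pwm)}\n")
            for row in pwm.matrix:
                fh.write(" " + " ".join(f"{p:.12f}" for p in row) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# Spacing enrichment

@dataclass
class SpacingTable:
    """Quadrant-resolved gap counts for one secondary motif.

    ``table`` has one row per observed (gap, quadrant) plus every tested cell,
    with columns gap, quadrant, count, p, p_corrected.  ``best`` is the row
    (as a dict) with the smallest corrected p-value among tested cells.
    """

    secondary: str
    n_sequences_with_both: int
    table: pd.DataFrame
    margin: int
    gap_range: int
    best: dict = field(default_factory=dict)
    primary_len: int = 0    # motif lengths after trimming, for composite inference
    secondary_len: int = 0

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["p_corrected"] < alpha]


def spacing_pvalue(x: int, n: int, p0: float, n_tests: int) -> tuple[float, float]:
    """Binomial upper-tail p for ``x`` of ``n`` hits at null rate ``p0``.

    Returns (p, Bonferroni-corrected p capped at 1).
    """
    if not (0 < p0 < 1):
        raise ValueError("p0 must lie strictly between 0 and 1")
    if not (0 <= x <= n):
        raise ValueError("x must lie in [0, n]")
    p = float(stats.binom.sf(x - 1, n, p0))  # P(X >= x)
    return p, min(1.0, p * n_tests)


def _quadrant(primary: MotifMatch, primary_len: int, sec_start: int,
              sec_end: int, sec_strand: str) -> tuple[str, int]:
    """Classify a secondary match relative to the primary's frame.

    The primary is oriented to + in its own frame; on a - strand primary the
    physical upstream/downstream sides swap.  The gap is the number of bases
    strictly between the two windows.
    """
    p_start, p_end = primary.start, primary.start + primary_len
    if sec_end <= p_start:
        side, gap = "upstream", p_start - sec_end
    elif sec_start >= p_end:
        side, gap = "downstream", sec_start - p_end
    else:
        raise ValueError("secondary window overlaps the primary")
    if primary.strand == "-":
        side = "downstream" if side == "upstream" else "upstream"
    rel = "same" if sec_strand == primary.strand else "opposite"
    return f"{side}-{rel}", gap


def spacing_analysis(
    peaks: Sequence[SequenceRecord],
    primary: PWM,
    secondaries: Sequence[PWM] | Mapping[str, PWM],
    margin: int = 150,
    gap_range: int = 20,
    minscore: float = 5.0,
    keep_primary: bool = True,
    trim_bits: float | None = 1.0,
) -> dict[str, SpacingTable]:
    """Spacing enrichment of secondary motifs around primary motif sites.

    For each peak whose best primary match scores at least ``minscore``, the
    best secondary match whose window lies entirely within ``margin`` bp of
    the primary (and does not overlap it) is binned by (gap, quadrant).  Gaps
    0..gap_range-1 are significance-tested per quadrant with a binomial tail
    against the uniform null p0 = 1/(4*(margin+1)); the Bonferroni factor is
    4*gap_range.  Deterministic given inputs.

    With ``keep_primary`` the primary motif itself is analysed as a secondary,
    enabling primary-primary spacings (the inverted-repeat case).
    """
    if isinstance(secondaries, Mapping):
        sec_list = [(name, pwm) for name, pwm in secondaries.items()]
    else:
        sec_list = [(pwm.name, pwm) for pwm in secondaries]
    if trim_bits is not None:
        primary = trim_motif(primary, trim_bits)
        sec_list = [(name, trim_motif(pwm, trim_bits)) for name, pwm in sec_list]
    if keep_primary and not any(np.array_equal(pwm.matrix, primary.matrix)
                                for _, pwm in sec_list):
        sec_list.append((primary.name, primary))

    lengths = {len(p) for p in peaks}
    if len(lengths) > 1:
        warnings.warn("peak sequences have unequal lengths; margins are per-peak",
                      stacklevel=2)

    cache: dict = {}
    primaries: list[tuple[SequenceRecord, MotifMatch]] = []
    for peak in peaks:
        m = best_match(peak, primary, minscore=minscore, _cache=cache)
        if m is not None:
            primaries.append((peak, m))
    if not primaries:
        raise ValueError("no peak passes the primary motif score threshold")

    p0 = 1.0 / (4.0 * (margin + 1))
    n_tests = 4 * gap_range
    results: dict[str, SpacingTable] = {}
    for sec_name, sec_pwm in sec_list:
        counts: dict[tuple[int, str], int] = {}
        contributors: dict[tuple[int, str], list] = {}
        n_both = 0
        w = len(sec_pwm)
        for peak, pm in primaries:
            scored = _all_scores(peak, sec_pwm, cache)
            if scored is None:
                continue
            plus, minus = scored
            p_start, p_end = pm.start, pm.start + len(primary)
            n_win = plus.size
            starts = np.arange(n_win)
            ends = starts + w
            # windows fully inside the margin on either side, non-overlapping
            upstream = (ends <= p_start) & (p_start - ends <= margin)
            downstream = (starts >= p_end) & (starts - p_end <= margin)
            allowed = upstream | downstream
            if not np.any(allowed):
                continue
            best_cell = None  # (score, start, strand_rank)
            for strand_rank, arr in enumerate((plus, minus)):
                masked = np.where(allowed, arr, -np.inf)
                i = int(np.argmax(masked))
                if not math.isfinite(masked[i]):
                    continue
                cand = (float(masked[i]), i, strand_rank)
                if best_cell is None or cand[0] > best_cell[0] or (
                    cand[0] == best_cell[0]
                    and (cand[1], cand[2]) < (best_cell[1], best_cell[2])
                ):
                    best_cell = cand
            if best_cell is None:
                continue
            score, s_start, s_rank = best_cell
            s_strand = "+-"[s_rank]
            quad, gap = _quadrant(pm, len(primary), s_start, s_start + w, s_strand)
            n_both += 1
            counts[(gap, quad)] = counts.get((gap, quad), 0) + 1
            contributors.setdefault((gap, quad), []).append(
                (peak, pm, MotifMatch(peak.id, s_start, s_strand, score, sec_name))
            )

        rows = []
        cells = set(counts) | {(g, q) for g in range(gap_range) for q in QUADRANTS}
        for gap, quad in sorted(cells):
            x = counts.get((gap, quad), 0)
            if gap < gap_range and n_both > 0:
                p, pc = spacing_pvalue(x, n_both, p0, n_tests)
            else:
                p, pc = float("nan"), float("nan")
            rows.append({"gap": gap, "quadrant": quad, "count": x,
                         "p": p, "p_corrected": pc})
        table = pd.DataFrame(rows)
        tested = table.dropna(subset=["p_corrected"])
        best = {}
        if len(tested):
            best_row = tested.sort_values(
                ["p_corrected", "gap", "quadrant"]).iloc[0]
            best = best_row.to_dict()
            best["contributors"] = contributors.get(
                (int(best_row["gap"]), best_row["quadrant"]), [])
        results[sec_name] = SpacingTable(
            secondary=sec_name, n_sequences_with_both=n_both, table=table,
            margin=margin, gap_range=gap_range, best=best,
            primary_len=len(primary), secondary_len=len(sec_pwm))
    return results


def infer_composite_pwm(
    contributors: Sequence[tuple[SequenceRecord, MotifMatch, MotifMatch]],
    primary_len: int,
    secondary_len: int,
    pseudocount: float = 0.1,
    name: str = "composite",
) -> PWM:
    """Infer a composite motif from peaks contributing to one enriched cell.

    Each contributing sequence is oriented so its primary match reads on the
    + strand; the window spanning primary + gap + secondary is stacked and
    column frequencies (with pseudocount) form the returned PWM.
    """
    if len(contributors) < 2:
        raise ValueError("need at least 2 contributing sequences")
    windows = []
    width = None
    for peak, pm, sm in contributors:
        lo = min(pm.start, sm.start)
        hi = max(pm.start + primary_len, sm.start + secondary_len)
        window = peak.sequence[lo:hi].upper()
        if pm.strand == "-":
            window = revcomp(window)
        if width is None:
            width = len(window)
        elif len(window) != width:
            raise ValueError(
                f"inconsistent window lengths ({len(window)} vs {width}) "
                f"in sequence {peak.id!r}")
        windows.append(window)
    counts = np.zeros((width, 4))
    for window in windows:
        for j, base in enumerate(window):
            if base in _CODE:
                counts[j, _CODE[base]] += 1
    return PWM.from_counts(counts, name=name, pseudocount=pseudocount)


# ---------------------------------------------------------------------------
# Inverted-repeat scanning

@dataclass(frozen=True)
class IRSite:
    """A located half-site pair: two intervals, the gap between them, and a label."""

    sequence_id: str
    left: tuple[int, int]
    right: tuple[int, int]
    gap: int
    orientation: str
    strand: str = "+"
    label: str = "custom"

    def __post_init__(self) -> None:
        if self.right[0] < self.left[1]:
            raise ValueError("half-site intervals overlap")
        if self.gap != self.right[0] - self.left[1]:
            raise ValueError("gap inconsistent with intervals")


def scan_inverted_repeats(
    seqs: Sequence[SequenceRecord],
    half_site: str = "AACAAT",
    gaps: Iterable[int] = range(0, 21),
    orientation: str = "inverted",
    label: str = "custom",
) -> list[IRSite]:
    """Exact-match scan for spaced repeats of a half-site (case-insensitive).

    For ``inverted`` orientation the element is half_site + g bases +
    revcomp(half_site); such an element reads identically (up to the spacer)
    on both strands, so a single forward scan finds every site.  For
    ``direct`` orientation the minus strand is scanned separately.
    """
    half = half_site.upper()
    if set(half) - set(_BASES):
        raise ValueError("half_site must be over ACGT")
    if orientation not in ("inverted", "direct"):
        raise ValueError("orientation must be 'inverted' or 'direct'")
    partner = revcomp(half) if orientation == "inverted" else half
    w = len(half)
    sites: list[IRSite] = []
    for seq in seqs:
        s = seq.sequence.upper()
        for gap in gaps:
            pattern = re.compile(
                "(?=" + re.escape(half) + "." * gap + re.escape(partner) + ")")
            for m in pattern.finditer(s):
                i = m.start()
                sites.append(IRSite(seq.id, (i, i + w), (i + w + gap, i + 2 * w + gap),
                                    gap, orientation, "+", label))
            if orientation == "direct":
                # direct repeats on the minus strand appear as revcomp pairs
                minus = re.compile(
                    "(?=" + re.escape(revcomp(half)) + "." * gap
                    + re.escape(revcomp(half)) + ")")
                for m in minus.finditer(s):
                    i = m.start()
                    sites.append(IRSite(seq.id, (i, i + w),
                                        (i + w + gap, i + 2 * w + gap),
                                        gap, orientation, "-", label))
    sites.sort(key=lambda site: (site.sequence_id, site.left[0], site.gap))
    return sites


def count_ir_regions(sites: Sequence[IRSite]) -> dict:
    """Count regions with at least one site, per label and overall unique.

    A region carrying sites of several labels counts once in ``unique``.
    """
    per_label: dict[str, set[str]] = {}
    all_regions: set[str] = set()
    for site in sites:
        per_label.setdefault(site.label, set()).add(site.sequence_id)
        all_regions.add(site.sequence_id)
    return {
        "per_label": {lbl: len(regs) for lbl, regs in sorted(per_label.items())},
        "unique": len(all_regions),
    }


def sites_to_bed(sites: Sequence[IRSite]) -> list[tuple[str, int, int, str, float, str]]:
    """IRSite list as BED6 rows (whole element, name = label, score 0)."""
    return [(s.sequence_id, s.left[0], s.right[1], s.label, 0.0, s.strand)
            for s in sites]
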
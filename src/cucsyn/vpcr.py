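"""Virtual PCR and sequence anchoring against draft-genome scaffolds.

A primer pair amplifies wherever the forward primer matches one strand and
the reverse primer's reverse complement lies downstream on the same strand
within the allowed product window, each primer matching with at most
``max_mismatch`` mismatches and none in the 3'-terminal ``clamp3`` bases.
Hits are reported in 1-based inclusive forward-strand coordinates.

The site search is seeded by the pigeonhole principle: with at most m
mismatches, at least one of m+1 primer slices matches exactly, so exact
slice occurrences (regex over IUPAC classes) generate the candidates and a
full comparison verifies them.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

logger = logging.getLogger(__name__)

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")
_ASSEMBLY_ALPHABET = set("ACGTN")


def revcomp(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def _check_primer(primer: str) -> str:
    primer = primer.upper()
    bad = set(primer) - set(IUPAC)
    if bad:
        raise ValueError(f"primer contains non-IUPAC symbols: {sorted(bad)}")
    if len(primer) < 15:
        raise ValueError("primer shorter than 15 nt")
    return primer


@dataclass
class Assembly:
    """A named draft assembly: scaffold id -> uppercase ACGTN sequence."""

    name: str
    scaffolds: dict[str, str]

    def __post_init__(self) -> None:
        if len(self.scaffolds) != len(set(self.scaffolds)):
            raise ValueError("duplicate scaffold ids")
        clean = {}
        for sid, seq in self.scaffolds.items():
            seq = seq.upper()
            if set(seq) - _ASSEMBLY_ALPHABET:
                raise ValueError(f"scaffold {sid}: alphabet must be ACGTN")
            clean[sid] = seq
        self.scaffolds = clean

    @classmethod
    def from_fasta(cls, path: str | Path, name: str | None = None) -> "Assembly":
        path = Path(path)
        records = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
        return cls(name or path.stem, records)

    def reverse_complemented(self) -> "Assembly":
        return Assembly(self.name + "_rc",
                        {sid: revcomp(s) for sid, s in self.scaffolds.items()})


@dataclass
class ScaffoldHit:
    marker_id: str
    assembly: str
    scaffold: str
    start: int  # 1-based inclusive, forward strand
    end: int
    strand: str  # strand carrying the forward primer: '+' or '-'
    product_size: int
    product_sequence: str = ""
    identity: float | None = None
    coverage: float | None = None


@dataclass
class VpcrParams:
    max_mismatch: int = 1
    clamp3: int = 3
    min_size: int = 40
    max_size: int = 5000


def _matches_at(seq: str, primer: str, pos: int, max_mismatch: int, clamp3: int) -> bool:
    """Does the primer match seq at pos (0-based) within tolerance?"""
    L = len(primer)
    if pos < 0 or pos + L > len(seq):
        return False
    mism = 0
    clamp_from = L - clamp3
    for k in range(L):
        if seq[pos + k] not in IUPAC[primer[k]]:
            if k >= clamp_from:
                return False  # 3' clamp must be exact
            mism += 1
            if mism > max_mismatch:
                return False
    return True


def _slice_regex(chunk: str) -> re.Pattern:
    return re.compile("".join(
        c if len(IUPAC[c]) == 1 else f"[{IUPAC[c]}]" for c in chunk
    ))


def find_primer_sites(
    seq: str, primer: str, max_mismatch: int = 1, clamp3: int = 3
) -> list[int]:
    """0-based start positions where the primer matches the given strand."""
    primer = _check_primer(primer)
    L = len(primer)
    n_parts = max_mismatch + 1
    bounds = [round(i * L / n_parts) for i in range(n_parts + 1)]
    candidates: set[int] = set()
    for i in range(n_parts):
        lo, hi = bounds[i], bounds[i + 1]
        chunk = primer[lo:hi]
        if all(len(IUPAC[c]) == 1 for c in chunk):
            # fast exact scan for non-degenerate slices
            p = seq.find(chunk)
            while p != -1:
                candidates.add(p - lo)
                p = seq.find(chunk, p + 1)
        else:
            pat = _slice_regex(chunk)
            for m in re.finditer(f"(?=({pat.pattern}))", seq):
                candidates.add(m.start() - lo)
    return sorted(
        p for p in candidates if _matches_at(seq, primer, p, max_mismatch, clamp3)
    )


def _products_one_orientation(
    seq: str, left: str, right: str, params: VpcrParams
) -> list[tuple[int, int]]:
    """(start0, end0exclusive) products: left primer then revcomp(right)."""
    left_sites = find_primer_sites(seq, left, params.max_mismatch, params.clamp3)
    if not left_sites:
        return []
    right_rc = revcomp(right)
    right_sites = find_primer_sites(seq, right_rc, params.max_mismatch, params.clamp3)
    out = []
    lf, lr = len(left), len(right_rc)
    for i in left_sites:
        for j in right_sites:
            end = j + lr
            size = end - i
            if size < lf + lr:
                continue  # overlapping primer footprints
            if params.min_size <= size <= params.max_size:
                out.append((i, end))
    return out


def virtual_pcr(
    marker_id: str,
    primer_fwd: str,
    primer_rev: str,
    assembly: Assembly,
    params: VpcrParams | None = None,
) -> list[ScaffoldHit]:
    """All virtual amplification products of a primer pair in an assembly."""
    params = params or VpcrParams()
    primer_fwd = _check_primer(primer_fwd)
    primer_rev = _check_primer(primer_rev)
    hits: list[ScaffoldHit] = []
    for sid in sorted(assembly.scaffolds):
        seq = assembly.scaffolds[sid]
        seen: set[tuple[int, int, str]] = set()
        for start0, end0 in _products_one_orientation(seq, primer_fwd, primer_rev, params):
            key = (start0, end0, "+")
            if key not in seen:
                seen.add(key)
                hits.append(ScaffoldHit(
                    marker_id, assembly.name, sid, start0 + 1, end0, "+",
                    end0 - start0, seq[start0:end0]))
        for start0, end0 in _products_one_orientation(seq, primer_rev, primer_fwd, params):
            key = (start0, end0, "-")
            if key not in seen:
                seen.add(key)
                hits.append(ScaffoldHit(
                    marker_id, assembly.name, sid, start0 + 1, end0, "-",
                    end0 - start0, seq[start0:end0]))
    hits.sort(key=lambda h: (h.scaffold, h.start, h.end, h.strand))
    return hits


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

NO_HIT = "no_hit"
UNIQUE = "unique"
MULTI_COPY = "multi_copy"
REPEAT_REGION = "repeat_region"


def classify_hits(
    hits_by_marker: dict[str, list[ScaffoldHit]],
    repeat_intervals: dict[str, list[tuple[int, int]]] | None = None,
) -> dict[str, str]:
    """no_hit / unique / multi_copy / repeat_region per marker.

    ``repeat_intervals`` maps scaffold id to 0-based half-open intervals
    (BED convention); a unique hit overlapping a repeat is demoted to
    repeat_region and excluded from anchoring downstream.
    """
    out: dict[str, str] = {}
    for marker, hits in hits_by_marker.items():
        if not hits:
            out[marker] = NO_HIT
        elif len(hits) > 1:
            out[marker] = MULTI_COPY
        else:
            h = hits[0]
            out[marker] = UNIQUE
            for s, e in (repeat_intervals or {}).get(h.scaffold, []):
                # hit as half-open: [start-1, end)
                if h.start - 1 < e and s < h.end:
                    out[marker] = REPEAT_REGION
                    break
    return out


# ---------------------------------------------------------------------------
# sequence anchoring (gapless seed-and-extend)
# ---------------------------------------------------------------------------

@dataclass
class SequenceAnchorParams:
    seed_len: int = 31
    min_identity: float = 0.9
    min_cov: float = 0.5


def anchor_by_sequence(
    marker_id: str,
    source_sequence: str,
    assembly: Assembly,
    params: SequenceAnchorParams | None = None,
) -> ScaffoldHit | str:
    """Place a gene/EST source sequence on an assembly, or return no_hit.

    Exact seed-and-extend: every shared ``seed_len``-mer defines a gapless
    diagonal; the full query is compared on each candidate diagonal and the
    best placement by identity x coverage wins.  Ties between distinct
    locations return ``multi_copy``.
    """
    params = params or SequenceAnchorParams()
    query = source_sequence.upper()
    if len(query) < 100:
        raise ValueError("source sequence shorter than 100 nt")
    if len(query) < params.seed_len:
        raise ValueError("source sequence shorter than the seed length")
    k = params.seed_len
    qkmers: dict[str, list[int]] = {}
    for i in range(len(query) - k + 1):
        qkmers.setdefault(query[i : i + k], []).append(i)

    candidates: set[tuple[str, int]] = set()  # (scaffold, diagonal offset)
    for sid in sorted(assembly.scaffolds):
        seq = assembly.scaffolds[sid]
        for j in range(len(seq) - k + 1):
            kmer = seq[j : j + k]
            if kmer in qkmers:
                for qi in qkmers[kmer]:
                    candidates.add((sid, j - qi))

    scored: list[tuple[float, float, float, str, int]] = []
    for sid, off in sorted(candidates):
        seq = assembly.scaffolds[sid]
        q_lo = max(0, -off)
        q_hi = min(len(query), len(seq) - off)
        span = q_hi - q_lo
        if span <= 0:
            continue
        matches = sum(
            1 for qi in range(q_lo, q_hi) if seq[off + qi] == query[qi]
        )
        identity = matches / span
        cov = span / len(query)
        if identity >= params.min_identity and cov >= params.min_cov:
            scored.append((identity * cov, identity, cov, sid, off))
    if not scored:
        return NO_HIT
    scored.sort(key=lambda t: (-t[0], t[3], t[4]))
    best = scored[0]
    ties = [s for s in scored[1:] if abs(s[0] - best[0]) < 1e-12]
    if ties:
        return MULTI_COPY
    _, identity, cov, sid, off = best
    q_lo = max(0, -off)
    q_hi = min(len(query), len(assembly.scaffolds[sid]) - off)
    start0, end0 = off + q_lo, off + q_hi
    return ScaffoldHit(
        marker_id, assembly.name, sid, start0 + 1, end0, "+",
        end0 - start0, assembly.scaffolds[sid][start0:end0],
        identity=identity, coverage=cov,
    )
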
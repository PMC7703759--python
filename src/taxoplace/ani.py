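"""Fragment-based average nucleotide identity and the species-assignment rule.

The query is cut into consecutive non-overlapping fragments; each fragment
is mapped to the reference by exact k-mer seeding on both strands followed
by ungapped scoring of the best seed diagonal.  ANI is the mean identity of
fragments that align at >= 80% identity; the alignment fraction (AF) is the
share of fragments that align.  A query is assigned to the species of the
best reference when AF exceeds the threshold (strict, default 65%) and the
ANI reaches that species' circumscription radius (inclusive, default 95%).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .errors import ValidationError

logger = logging.getLogger(__name__)

DEFAULT_K = 16
DEFAULT_FRAGMENT_LEN = 3000
DEFAULT_AF_THRESHOLD = 0.65
DEFAULT_RADIUS_PCT = 95.0
MIN_FRAGMENT_IDENTITY = 0.8

#: k-mers occurring more often than this in the reference are skipped as seeds
_MAX_KMER_OCCURRENCES = 100

_CODE = np.full(256, 255, dtype=np.uint8)
for i, base in enumerate("ACGT"):
    _CODE[ord(base)] = i
    _CODE[ord(base.lower())] = i

SeqSet = Union[str, Sequence[str], Mapping[str, str]]


@dataclass(frozen=True)
class ANIResult:
    """Query-vs-one-reference ANI estimate."""

    reference_id: str
    ani_pct: Optional[float]  # None when nothing aligned
    align_frac: float
    n_fragments: int = 0
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.align_frac == 0 and self.ani_pct is not None:
            raise ValidationError("ani_pct must be None when align_frac is 0")


@dataclass(frozen=True)
class SpeciesRadius:
    """Per-species ANI circumscription radius around a representative genome."""

    species_name: str
    representative_genome: str
    radius_pct: float = DEFAULT_RADIUS_PCT

    def __post_init__(self) -> None:
        if not (50 < self.radius_pct <= 100):
            raise ValidationError(
                f"radius_pct must be in (50, 100], got {self.radius_pct}")


def _as_contigs(seqs: SeqSet) -> list[str]:
    if isinstance(seqs, str):
        return [seqs]
    if isinstance(seqs, Mapping):
        return [seqs[k] for k in seqs]
    return list(seqs)


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Integer codes of all k-mers; -1 where the window has an invalid base."""
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    out = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for i in range(k):
        window = codes[i:i + n]
        out = (out << 2) | (window & 3)
        valid &= window < 4
    out[~valid] = -1
    return out


class _ReferenceIndex:
    """Sorted k-mer index over the concatenated reference contigs."""

    def __init__(self, seqs: SeqSet, k: int):
        contigs = _as_contigs(seqs)
        if not contigs or all(len(c) == 0 for c in contigs):
            raise ValidationError("reference genome is empty")
        sep = np.full(k, 255, dtype=np.uint8)  # kills cross-contig k-mers
        parts = []
        for i, contig in enumerate(contigs):
            if i:
                parts.append(sep)
            parts.append(_encode(contig))
        self.codes = np.concatenate(parts)
        self.k = k
        kmers = _kmer_codes(self.codes, k)
        pos = np.nonzero(kmers >= 0)[0]
        order = np.argsort(kmers[pos], kind="stable")
        self.sorted_kmers = kmers[pos][order]
        self.sorted_pos = pos[order].astype(np.int64)

    def best_diagonal(self, frag_kmers: np.ndarray) -> tuple[Optional[int], int]:
        """Diagonal (ref_start - frag_start) with the most seed hits."""
        valid = np.nonzero(frag_kmers >= 0)[0]
        if valid.size == 0:
            return None, 0
        fk = frag_kmers[valid]
        left = np.searchsorted(self.sorted_kmers, fk, side="left")
        right = np.searchsorted(self.sorted_kmers, fk, side="right")
        counts = right - left
        usable = np.nonzero((counts > 0) & (counts <= _MAX_KMER_OCCURRENCES))[0]
        if usable.size == 0:
            return None, 0
        diags = np.concatenate([
            self.sorted_pos[left[i]:right[i]] - valid[i] for i in usable
        ])
        uniq, n = np.unique(diags, return_counts=True)
        best = int(np.argmax(n))
        return int(uniq[best]), int(n[best])


def _revcomp_codes(codes: np.ndarray) -> np.ndarray:
    out = codes[::-1].copy()
    ok = out < 4
    out[ok] = 3 - out[ok]
    return out


def _diagonal_identity(frag: np.ndarray, ref: np.ndarray, diag: int) -> float:
    """Matches / fragment length for an ungapped alignment at ``diag``."""
    flen = frag.size
    lo = max(0, -diag)
    hi = min(flen, ref.size - diag)
    if hi <= lo:
        return 0.0
    f = frag[lo:hi]
    r = ref[lo + diag:hi + diag]
    matches = int(np.count_nonzero((f == r) & (f < 4)))
    return matches / flen


def fragment_ani(query: SeqSet, reference: SeqSet, *,
                 k: int = DEFAULT_K,
                 fragment_len: int = DEFAULT_FRAGMENT_LEN,
                 min_identity: float = MIN_FRAGMENT_IDENTITY,
                 reference_id: str = "reference") -> ANIResult:
    """One-directional (query -> reference) fragment ANI and AF."""
    if fragment_len < 10 * k:
        raise ValidationError(f"fragment_len must be >= 10*k = {10 * k}")
    contigs = [c for c in _as_contigs(query) if c]
    if not contigs:
        raise ValidationError("query genome is empty")

    warnings: list[str] = []
    fragments: list[np.ndarray] = []
    for contig in contigs:
        codes = _encode(contig)
        for start in range(0, codes.size - fragment_len + 1, fragment_len):
            fragments.append(codes[start:start + fragment_len])
    if not fragments:
        # genome shorter than one fragment: keep a single truncated fragment
        longest = max(contigs, key=len)
        fragments.append(_encode(longest))
        warnings.append(
            f"genome shorter than one {fragment_len} bp fragment; "
            f"using a single {len(longest)} bp fragment")

    index = _ReferenceIndex(reference, k)
    identities: list[float] = []
    n_aligned = 0
    for frag in fragments:
        fwd = _kmer_codes(frag, k)
        diag_f, hits_f = index.best_diagonal(fwd)
        rc = _revcomp_codes(frag)
        diag_r, hits_r = index.best_diagonal(_kmer_codes(rc, k))
        if diag_f is None and diag_r is None:
            continue
        if hits_r > hits_f:
            ident = _diagonal_identity(rc, index.codes, diag_r)
        else:
            ident = _diagonal_identity(frag, index.codes, diag_f)
        if ident >= min_identity:
            identities.append(ident)
            n_aligned += 1

    total = len(fragments)
    af = n_aligned / total
    ani = 100.0 * float(np.mean(identities)) if identities else None
    return ANIResult(reference_id=reference_id, ani_pct=ani, align_frac=af,
                     n_fragments=total, warnings=tuple(warnings))


def species_assign(ani_results: Sequence[ANIResult],
                   radii: Mapping[str, SpeciesRadius],
                   af_threshold: float = DEFAULT_AF_THRESHOLD) -> Optional[str]:
    """Assign a query to the species of its closest reference, or not.

    Keeps results whose alignment fraction strictly exceeds ``af_threshold``;
    among those picks the highest ANI (ties to the lexicographically smallest
    species name) and assigns iff that ANI is >= the species' radius.
    """
    by_rep = {r.representative_genome: r for r in radii.values()}
    candidates = []
    for res in ani_results:
        if res.ani_pct is None or res.align_frac <= af_threshold:
            continue
        radius = by_rep.get(res.reference_id)
        if radius is None:
            logger.warning("no radius entry for reference %s; skipping",
                           res.reference_id)
            continue
        candidates.append((res, radius))
    if not candidates:
        return None
    best_ani = max(res.ani_pct for res, _ in candidates)
    top = [(res, rad) for res, rad in candidates if res.ani_pct == best_ani]
    if len(top) > 1:
        top.sort(key=lambda pair: pair[1].species_name)
        logger.warning("ANI tie at %.2f%%; keeping %s", best_ani,
                       top[0][1].species_name)
    res, radius = top[0]
    if res.ani_pct >= radius.radius_pct:
        return radius.species_name
    return None


def best_hit(ani_results: Sequence[ANIResult],
             af_threshold: float = DEFAULT_AF_THRESHOLD) -> Optional[ANIResult]:
    """The AF-passing result with the highest ANI, if any."""
    passing = [r for r in ani_results
               if r.ani_pct is not None and r.align_frac > af_threshold]
    if not passing:
        return None
    return max(passing, key=lambda r: (r.ani_pct, r.reference_id))


def write_ani_table(results: Mapping[str, Sequence[ANIResult]], path) -> None:
    """Dump all pairwise ANI results (query, reference, ani, af)."""
    with open(path, "w") as fh:
        fh.write("query\treference\tani_pct\talign_frac\tn_fragments\n")
        for qid in sorted(results):
            for res in results[qid]:
                ani = "" if res.ani_pct is None else f"{res.ani_pct:.3f}"
                fh.write(f"{qid}\t{res.reference_id}\t{ani}\t"
                         f"{res.align_frac:.4f}\t{res.n_fragments}\n")
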
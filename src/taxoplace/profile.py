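"""Marker-table handling: domain assignment, concatenation/masking, QC.

Marker identification itself (gene calling + HMM search) is out of scope;
this module consumes hit tables with pre-aligned per-marker rows, in the
shape an aligner would emit them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

from .errors import FormatError, ValidationError
from .place import GAP, AlignedQuery

DEFAULT_MIN_COMPLETENESS = 50.0
DEFAULT_MAX_CONTAMINATION = 10.0

DOMAIN_BACTERIA = "d__Bacteria"
DOMAIN_ARCHAEA = "d__Archaea"
DOMAIN_AMBIGUOUS = "ambiguous"
DOMAIN_UNDETERMINED = "undetermined"


@dataclass
class MarkerHit:
    present: bool
    row: Optional[str] = None  # aligned amino acids + gaps, fixed marker width


@dataclass
class MarkerHitTable:
    """genome id -> marker id -> hit, plus the fixed marker widths."""

    widths: dict[str, int]
    hits: dict[str, dict[str, MarkerHit]] = field(default_factory=dict)

    def marker_order(self) -> list[str]:
        return list(self.widths)

    def row_for(self, genome: str, marker: str) -> Optional[str]:
        hit = self.hits.get(genome, {}).get(marker)
        return hit.row if hit and hit.present else None

    def n_present(self, genome: str) -> int:
        return sum(1 for h in self.hits.get(genome, {}).values() if h.present)


@dataclass(frozen=True)
class ColumnMask:
    """Boolean keep-mask over the concatenated alignment columns."""

    marker_set: str
    keep: tuple[bool, ...]

    @property
    def width(self) -> int:
        return len(self.keep)

    @property
    def kept_width(self) -> int:
        return sum(self.keep)


@dataclass(frozen=True)
class GenomeQuality:
    genome_id: str
    completeness_pct: float
    contamination_pct: float

    def __post_init__(self) -> None:
        if not (0 <= self.completeness_pct <= 100):
            raise ValidationError(
                f"completeness out of range: {self.completeness_pct}")
        if self.contamination_pct < 0:
            raise ValidationError(
                f"negative contamination: {self.contamination_pct}")


def assign_domain(bac_hits: int, bac_total: int,
                  arc_hits: int, arc_total: int) -> tuple[str, list[str]]:
    """Pick the domain with the higher proportion of identified markers.

    Returns (domain label, warnings).  Equal non-zero proportions yield
    ``ambiguous``; no hits at all yields ``undetermined``.
    """
    if bac_total <= 0 or arc_total <= 0:
        raise ValidationError("marker totals must be positive")
    if bac_hits < 0 or arc_hits < 0:
        raise ValidationError("negative hit counts")
    bac_prop = bac_hits / bac_total
    arc_prop = arc_hits / arc_total
    if bac_prop == 0 and arc_prop == 0:
        return DOMAIN_UNDETERMINED, ["no marker genes identified"]
    if bac_prop > arc_prop:
        return DOMAIN_BACTERIA, []
    if arc_prop > bac_prop:
        return DOMAIN_ARCHAEA, []
    return DOMAIN_AMBIGUOUS, [
        f"equal marker proportions ({bac_prop:.3f}); domain ambiguous"]


def concat_and_mask(rows: Mapping[str, Optional[str]],
                    marker_order: Sequence[str],
                    widths: Mapping[str, int],
                    mask: ColumnMask,
                    genome_id: str = "query") -> AlignedQuery:
    """Concatenate per-marker rows (gap-filling absences) and apply the mask."""
    parts: list[str] = []
    for marker in marker_order:
        width = widths[marker]
        row = rows.get(marker)
        if row is None:
            parts.append(GAP * width)
        else:
            if len(row) != width:
                raise ValidationError(
                    f"marker {marker!r}: row width {len(row)} != declared {width}")
            parts.append(row)
    concat = "".join(parts)
    if len(concat) != mask.width:
        raise ValidationError(
            f"concatenated width {len(concat)} != mask width {mask.width}")
    masked = "".join(ch for ch, keep in zip(concat, mask.keep) if keep)
    return AlignedQuery(genome_id=genome_id, row=masked)


def qc_filter(quality: GenomeQuality,
              min_completeness: float = DEFAULT_MIN_COMPLETENESS,
              max_contamination: float = DEFAULT_MAX_CONTAMINATION) -> bool:
    """Recommended quality gate: completeness >= min AND contamination <= max.

    Both boundaries are inclusive.  Callers treat a failure as advisory
    unless running with --strict-qc.
    """
    if min_completeness < 0 or max_contamination < 0:
        raise ValidationError("QC thresholds must be non-negative")
    return (quality.completeness_pct >= min_completeness
            and quality.contamination_pct <= max_contamination)


# ---------------------------------------------------------------------------
# File formats (marker hits TSV, 0/1 mask line, CheckM-style quality TSV)
# ---------------------------------------------------------------------------


def read_marker_hits(path) -> MarkerHitTable:
    """TSV columns: genome, marker, present (0/1), aligned_row (optional)."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise FormatError(f"empty marker hits file {path}")
    header = lines[0].split("\t")
    if header[:3] != ["genome", "marker", "present"]:
        raise FormatError("marker hits header must start with genome/marker/present")
    widths: dict[str, int] = {}
    hits: dict[str, dict[str, MarkerHit]] = {}
    for ln in lines[1:]:
        if not ln.strip():
            continue
        parts = ln.split("\t")
        genome, marker, present = parts[0], parts[1], parts[2] == "1"
        row = parts[3] if len(parts) > 3 and parts[3] else None
        if row is not None:
            if marker in widths and widths[marker] != len(row):
                raise ValidationError(
                    f"marker {marker!r} width conflict in {path}")
            widths.setdefault(marker, len(row))
        hits.setdefault(genome, {})[marker] = MarkerHit(present=present, row=row)
    return MarkerHitTable(widths=widths, hits=hits)


def write_marker_hits(table: MarkerHitTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("genome\tmarker\tpresent\taligned_row\n")
        for genome in sorted(table.hits):
            for marker in table.marker_order():
                hit = table.hits[genome].get(marker)
                if hit is None:
                    continue
                fh.write(f"{genome}\t{marker}\t{int(hit.present)}\t"
                         f"{hit.row or ''}\n")


def read_mask(path, marker_set: str = "default") -> ColumnMask:
    """Read a mask stored as a single line of 0/1 characters."""
    text = Path(path).read_text().strip()
    if not text or set(text) - {"0", "1"}:
        raise FormatError(f"mask file {path} must be a single 0/1 line")
    return ColumnMask(marker_set=marker_set,
                      keep=tuple(ch == "1" for ch in text))


def write_mask(mask: ColumnMask, path) -> None:
    Path(path).write_text("".join("1" if k else "0" for k in mask.keep) + "\n")


def read_quality(path) -> dict[str, GenomeQuality]:
    """TSV columns: genome, completeness, contamination (CheckM-style)."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise FormatError(f"empty quality file {path}")
    out: dict[str, GenomeQuality] = {}
    for ln in lines[1:]:
        if not ln.strip():
            continue
        genome, comp, cont = ln.split("\t")[:3]
        out[genome] = GenomeQuality(genome_id=genome,
                                    completeness_pct=float(comp),
                                    contamination_pct=float(cont))
    return out
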
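"""Readers and writers for the text formats the caller touches.

Input: samtools text pileup (one file per sequencing replicate) or "depth
chart" tables — tab-delimited per-position counts of each nucleotide, the
intermediate format the model consumes.  Output: depth charts and a minimal
VCF 4.2 with the test statistics in INFO.

Coordinates are 1-based in every format handled here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .model import BASES, InputError, ReadCountMatrix
from .testing import VariantCall

__all__ = [
    "DepthChartRecord",
    "read_pileup",
    "read_depth_chart",
    "write_depth_chart",
    "assemble_count_matrix",
    "write_vcf",
]

logger = logging.getLogger("rarevar")

_DC_HEADER = ["chrom", "pos", "ref", "A", "C", "G", "T"]


@dataclass
class DepthChartRecord:
    """Per-position nucleotide counts for one replicate."""

    chrom: str
    pos: int
    ref: str
    count_A: int
    count_C: int
    count_G: int
    count_T: int

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise InputError(f"position must be 1-based, got {self.pos}")
        if self.ref not in BASES:
            raise InputError(f"reference base must be one of {BASES}, got {self.ref!r}")
        for base in BASES:
            if getattr(self, f"count_{base}") < 0:
                raise InputError(f"negative count at {self.chrom}:{self.pos}")

    @property
    def counts(self):
        return np.array([getattr(self, f"count_{b}") for b in BASES], dtype=np.int64)

    @property
    def depth(self) -> int:
        return int(self.counts.sum())


# ---------------------------------------------------------------------------
# samtools text pileup
# ---------------------------------------------------------------------------


def _parse_read_bases(bases: str, ref: str, line_no: int):
    """Count A/C/G/T in a pileup read-bases string.

    '.' and ',' count toward the reference; explicit letters toward their
    base (case pooled — the model uses strand-insensitive counts); '^' with
    its mapping-quality character, '$', indel runs '+k'/'-k', '*', 'N' and
    reference skips '>'/'<' are consumed without contributing counts.
    """
    counts = dict.fromkeys(BASES, 0)
    i = 0
    length = len(bases)
    while i < length:
        c = bases[i]
        if c == "^":
            i += 2  # skip the mapping-quality character
            continue
        if c in "$*><":
            i += 1
            continue
        if c in "+-":
            i += 1
            start = i
            while i < length and bases[i].isdigit():
                i += 1
            if i == start:
                raise InputError(f"malformed indel at line {line_no}")
            i += int(bases[start:i])  # skip the inserted/deleted sequence
            continue
        if c in ".,":
            counts[ref] += 1
        else:
            upper = c.upper()
            if upper in BASES:
                counts[upper] += 1
            elif upper != "N":
                raise InputError(
                    f"unrecognized pileup base character {c!r} at line {line_no}"
                )
        i += 1
    return counts


def read_pileup(stream):
    """Parse a samtools text pileup stream into depth-chart records.

    Expects the six-column layout (chrom, 1-based pos, ref, depth,
    read-bases, qualities); the depth column is checked against the parsed
    counts and a disagreement logs a warning — the parsed counts win,
    because indels, 'N' and reference skips are deliberately excluded.
    """
    records = []
    for line_no, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) == 1:
            fields = line.split()
        if len(fields) < 4:
            raise InputError(f"malformed pileup line {line_no}: {line!r}")
        chrom, pos_s, ref = fields[0], fields[1], fields[2].upper()
        try:
            pos = int(pos_s)
            depth = int(fields[3])
        except ValueError as exc:
            raise InputError(f"malformed pileup line {line_no}: {line!r}") from exc
        if ref not in BASES:
            raise InputError(
                f"reference base {ref!r} not in {BASES} at pileup line {line_no}"
            )
        bases = fields[4] if len(fields) > 4 else ""
        counts = _parse_read_bases(bases, ref, line_no)
        parsed_depth = sum(counts.values())
        if parsed_depth != depth:
            logger.warning(
                "pileup line %d: depth column %d disagrees with %d parsed bases; "
                "using parsed counts",
                line_no,
                depth,
                parsed_depth,
            )
        records.append(
            DepthChartRecord(
                chrom=chrom,
                pos=pos,
                ref=ref,
                **{f"count_{b}": counts[b] for b in BASES},
            )
        )
    return records


# ---------------------------------------------------------------------------
# depth chart tables
# ---------------------------------------------------------------------------


def write_depth_chart(records, stream) -> None:
    """Write records as a tab-delimited depth chart (header included)."""
    stream.write("\t".join(_DC_HEADER) + "\n")
    for rec in records:
        stream.write(
            "\t".join(
                [
                    rec.chrom,
                    str(rec.pos),
                    rec.ref,
                    str(rec.count_A),
                    str(rec.count_C),
                    str(rec.count_G),
                    str(rec.count_T),
                ]
            )
            + "\n"
        )


def read_depth_chart(stream):
    """Read a tab-delimited depth chart written by :func:`write_depth_chart`."""
    records = []
    header = None
    for line_no, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if header is None:
            if fields != _DC_HEADER:
                raise InputError(
                    f"bad depth chart header at line {line_no}: expected "
                    f"{_DC_HEADER}, got {fields}"
                )
            header = fields
            continue
        if len(fields) != len(_DC_HEADER):
            raise InputError(f"wrong column count at depth chart line {line_no}")
        chrom, pos_s, ref = fields[0], fields[1], fields[2]
        try:
            pos = int(pos_s)
            counts = [int(x) for x in fields[3:7]]
        except ValueError as exc:
            raise InputError(
                f"non-integer field at depth chart line {line_no}"
            ) from exc
        try:
            records.append(
                DepthChartRecord(
                    chrom=chrom,
                    pos=pos,
                    ref=ref,
                    **{f"count_{b}": c for b, c in zip(BASES, counts)},
                )
            )
        except InputError as exc:
            raise InputError(f"depth chart line {line_no}: {exc}") from exc
    return records


# ---------------------------------------------------------------------------
# count-matrix assembly
# ---------------------------------------------------------------------------


def assemble_count_matrix(replicate_records) -> ReadCountMatrix:
    """Combine per-replicate depth-chart records into a ReadCountMatrix.

    Positions are the sorted union across replicates; a position absent
    from a replicate contributes zero depth there.  All replicates must
    agree on the chromosome and on the reference base at shared positions.
    """
    if not replicate_records:
        raise InputError("no replicates given")
    chroms = set()
    ref_by_pos: dict[int, str] = {}
    for replicate in replicate_records:
        for rec in replicate:
            chroms.add(rec.chrom)
            prev = ref_by_pos.get(rec.pos)
            if prev is not None and prev != rec.ref:
                raise InputError(
                    f"conflicting reference base at position {rec.pos}: "
                    f"{prev} vs {rec.ref}"
                )
            ref_by_pos[rec.pos] = rec.ref
    if len(chroms) > 1:
        raise InputError(f"replicates span multiple chromosomes: {sorted(chroms)}")
    if not ref_by_pos:
        raise InputError("no positions in any replicate")
    chrom = chroms.pop()
    positions = np.array(sorted(ref_by_pos), dtype=np.int64)
    index = {p: j for j, p in enumerate(positions)}
    J, N = len(positions), len(replicate_records)
    base_counts = np.zeros((J, N, 4), dtype=np.int64)
    for i, replicate in enumerate(replicate_records):
        for rec in replicate:
            base_counts[index[rec.pos], i, :] = rec.counts
    reference_base = np.array([ref_by_pos[p] for p in positions], dtype="<U1")
    return ReadCountMatrix.from_base_counts(
        positions=positions,
        reference_base=reference_base,
        base_counts=base_counts,
        chrom=chrom,
    )


# ---------------------------------------------------------------------------
# VCF output
# ---------------------------------------------------------------------------

_VCF_INFO = (
    '##INFO=<ID=NRAF_CASE,Number=1,Type=Float,Description="Posterior mean '
    'non-reference allele frequency in the case sample">\n'
    '##INFO=<ID=NRAF_CTRL,Number=1,Type=Float,Description="Posterior mean '
    'non-reference allele frequency in the control sample">\n'
    '##INFO=<ID=DIFFPROB,Number=1,Type=Float,Description="Posterior '
    'probability that the case-control difference exceeds tau">\n'
    '##INFO=<ID=CHI2P,Number=1,Type=Float,Description="P-value of the '
    'chi-square non-uniform base distribution test">\n'
    '##FILTER=<ID=chi2_uniform,Description="Provisional variant whose '
    'non-reference base counts are consistent with uniform error">\n'
)


def _alt_base(case_counts: ReadCountMatrix, j: int) -> str:
    """Most frequent pooled non-reference base; ties break A < C < G < T."""
    labels = case_counts.nonref_base_labels()[j]
    counts = case_counts.nonref_base_counts()[j]
    return labels[int(np.argmax(counts))]  # argmax keeps first = lowest base


def write_vcf(
    calls,
    case_counts: ReadCountMatrix,
    meta: dict | None,
    stream,
    emit_filtered: bool = False,
) -> None:
    """Write called variants as minimal VCF 4.2.

    One record per called variant; with ``emit_filtered``, provisional
    positions that failed the chi-square promotion are emitted with
    FILTER=chi2_uniform.
    """
    meta = meta or {}
    stream.write("##fileformat=VCFv4.2\n")
    stream.write("##source=rarevar\n")
    for key, value in meta.items():
        stream.write(f"##{key}={value}\n")
    stream.write(_VCF_INFO)
    stream.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
    index = {int(p): j for j, p in enumerate(case_counts.positions)}
    for call in calls:
        if not isinstance(call, VariantCall):
            raise InputError("calls must be VariantCall instances")
        emit_as_filtered = emit_filtered and call.provisional and not call.called
        if not (call.called or emit_as_filtered):
            continue
        j = index.get(call.position)
        if j is None:
            raise InputError(f"call position {call.position} not in case counts")
        ref = case_counts.reference_base[j]
        alt = _alt_base(case_counts, j)
        chi2_txt = f"{call.chi2_p:.6g}" if call.chi2_p is not None else "."
        info = (
            f"NRAF_CASE={call.nraf_case:.6g};NRAF_CTRL={call.nraf_control:.6g};"
            f"DIFFPROB={call.diff_prob:.6g};CHI2P={chi2_txt}"
        )
        filt = "PASS" if call.called else "chi2_uniform"
        stream.write(
            f"{case_counts.chrom}\t{call.position}\t.\t{ref}\t{alt}\t.\t{filt}\t{info}\n"
        )
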
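"""Alignment and coordinate-table I/O, core-region extraction, coordinate maps.

The central container is :class:`AlignmentBlock`, one gap-aware multi-strain
aligned region (a local colinear block, LCB) with per-strain genome anchors.
Internally every coordinate is 0-based half-open; XMFA and coords files use the
1-based inclusive conventions of their formats and are converted on read/write.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, MissingDataError
from .seqcodes import revcomp, rows_from_strings, rows_to_strings

log = logging.getLogger(__name__)

GAP = b"-"

#: anchor = (genome start, genome end, strand), 0-based half-open, strand '+'/'-'
Anchor = tuple


@dataclass
class AlignmentBlock:
    """A multi-strain aligned region with per-strain genome coordinates.

    ``rows`` is an (n_strains, length) ``|S1`` array over {A,C,G,T,-,N}, stored
    in alignment orientation. ``anchors`` maps each strain to (start, end,
    strand) on its own genome, 0-based half-open; the ungapped row length must
    equal ``end - start``.
    """

    strain_ids: list
    rows: np.ndarray
    anchors: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.rows.ndim != 2 or self.rows.shape[0] != len(self.strain_ids):
            raise FormatError("row matrix does not match strain list")
        for sid in self.strain_ids:
            if sid not in self.anchors:
                self.anchors[sid] = (0, int((self.row(sid) != GAP).sum()), "+")

    @property
    def n_strains(self) -> int:
        return len(self.strain_ids)

    @property
    def length(self) -> int:
        return self.rows.shape[1]

    def index(self, strain) -> int:
        try:
            return self.strain_ids.index(strain)
        except ValueError:
            raise MissingDataError(f"strain {strain!r} not in block") from None

    def row(self, strain) -> np.ndarray:
        return self.rows[self.index(strain)]

    @classmethod
    def from_strings(cls, strain_ids, seqs, anchors=None) -> "AlignmentBlock":
        return cls(list(strain_ids), rows_from_strings(seqs), dict(anchors or {}))


def column_to_genome(block: AlignmentBlock, strain, column: int) -> int:
    """Genome position (0-based) of the non-gap residue at or left of ``column``.

    Strand-aware: on '-' anchored rows positions decrease with the column index.
    """
    if not 0 <= column < block.length:
        raise IndexError(f"column {column} outside block of length {block.length}")
    row = block.row(strain)
    ungapped = int((row[: column + 1] != GAP).sum())
    offset = max(ungapped - 1, 0)
    start, end, strand = block.anchors[strain]
    if strand == "-":
        return end - 1 - offset
    return start + offset


_XMFA_HEADER = re.compile(r"^>\s*(\S+):(\d+)-(\d+)\s+([+-])")


def read_xmfa(path) -> list:
    """Parse a Mauve-dialect XMFA file into a list of AlignmentBlocks.

    Each block is terminated by a '=' line; entry headers are
    ``> seqid:start-end strand``. Rows anchored on the '-' strand are stored
    reverse-complemented into alignment orientation, anchors preserved.
    """
    blocks = []
    ids, seqs, anchors = [], [], {}
    cur_id, cur_parts, cur_line = None, [], 0

    def close_entry():
        nonlocal cur_id, cur_parts
        if cur_id is None:
            return
        sid, start1, end1, strand = cur_id
        seq = "".join(cur_parts)
        if strand == "-":
            seq = revcomp(seq)
        if sid in anchors:
            raise FormatError(f"duplicate strain {sid!r} in block", line=cur_line)
        ids.append(sid)
        seqs.append(seq)
        anchors[sid] = (start1 - 1, end1, strand)
        cur_id, cur_parts = None, []

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("="):
                close_entry()
                if ids:
                    lengths = {len(s) for s in seqs}
                    if len(lengths) > 1:
                        raise FormatError("ragged block: unequal row lengths", line=lineno)
                    blocks.append(AlignmentBlock.from_strings(ids, seqs, anchors))
                ids, seqs, anchors = [], [], {}
            elif line.startswith(">"):
                close_entry()
                m = _XMFA_HEADER.match(line)
                if not m:
                    raise FormatError(f"bad XMFA header {line!r}", line=lineno)
                sid, s, e, strand = m.group(1), int(m.group(2)), int(m.group(3)), m.group(4)
                if strand not in "+-":
                    raise FormatError(f"unknown strand token {strand!r}", line=lineno)
                cur_id, cur_line = (sid, s, e, strand), lineno
            else:
                if cur_id is None:
                    raise FormatError("sequence data outside an entry", line=lineno)
                cur_parts.append(line)
    if cur_id is not None or ids:
        close_entry()
        if ids:
            lengths = {len(s) for s in seqs}
            if len(lengths) > 1:
                raise FormatError("ragged block: unequal row lengths")
            blocks.append(AlignmentBlock.from_strings(ids, seqs, anchors))
    return blocks


def write_xmfa(blocks, path, provenance=None, width=80):
    """Write AlignmentBlocks as XMFA; '-' rows are reverse-complemented back."""
    with open(path, "w") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        for block in blocks:
            for sid, seq in zip(block.strain_ids, rows_to_strings(block.rows)):
                start, end, strand = block.anchors[sid]
                if strand == "-":
                    seq = revcomp(seq)
                fh.write(f"> {sid}:{start + 1}-{end} {strand}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")
            fh.write("=\n")


def write_fasta(block: AlignmentBlock, path, provenance=None, width=80):
    with open(path, "w") as fh:
        if provenance:
            fh.write(f"; {provenance}\n")
        for sid, seq in zip(block.strain_ids, rows_to_strings(block.rows)):
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def extract_core(blocks, min_len=500, strain_ids=None, max_gap_frac=0.5) -> list:
    """Keep blocks aligned for all genomes over at least ``min_len`` columns.

    A block passes when every strain of the universe is present, contributes at
    least one non-gap residue, has at most ``max_gap_frac`` gaps in its row, and
    the block is at least ``min_len`` alignment columns long. The 50% gap guard
    is this package's reading of "aligned for all genomes" and is logged.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    blocks = list(blocks)
    if not blocks:
        return []
    universe = set(strain_ids) if strain_ids is not None else set().union(
        *(set(b.strain_ids) for b in blocks)
    )
    core = []
    for b in blocks:
        if not universe <= set(b.strain_ids):
            log.debug("core filter: block dropped, missing strains")
            continue
        if b.length < min_len:
            continue
        gapfrac = (b.rows == GAP).mean(axis=1)
        nongap = (b.rows != GAP).any(axis=1)
        if nongap.all() and (gapfrac <= max_gap_frac).all():
            core.append(b)
        else:
            log.debug("core filter: block dropped by gap guard (max_gap_frac=%s)", max_gap_frac)
    return core


COORDS_COLUMNS = [
    "ref_start",
    "ref_end",
    "qry_start",
    "qry_end",
    "ref_len",
    "qry_len",
    "pct_identity",
]


def read_coords(path) -> pd.DataFrame:
    """Parse a tab-delimited show-coords-style table into a CoordsTable frame.

    Header/banner lines are skipped; a data line starts with an integer field.
    Coordinates are 1-based inclusive as printed; reference intervals are
    normalized so ref_end >= ref_start.
    """
    records = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = re.split(r"\s+", line)
            if not re.fullmatch(r"-?\d+", fields[0]):
                continue  # banner / header line
            if len(fields) < 7:
                raise FormatError("coords line has fewer than 7 fields", line=lineno)
            try:
                nums = [float(x) for x in fields[:7]]
            except ValueError:
                raise FormatError(f"malformed numeric field in {fields[:7]}", line=lineno) from None
            rs, re_, qs, qe, rl, ql, pid = nums
            if rs > re_:
                rs, re_ = re_, rs
            records.append((int(rs), int(re_), int(qs), int(qe), int(rl), int(ql), pid))
    df = pd.DataFrame(records, columns=COORDS_COLUMNS)
    if ((df["pct_identity"] < 0) | (df["pct_identity"] > 100)).any():
        raise FormatError("pct_identity outside [0, 100]")
    return df


def partition_pangenome(presence: pd.DataFrame):
    """Split a genes x strains boolean presence matrix into (core, accessory).

    Core genes are present in every strain; accessory genes are the complement.
    """
    if presence.empty:
        raise MissingDataError("empty presence matrix")
    present_everywhere = presence.all(axis=1)
    if not presence.any(axis=1).all():
        raise FormatError("gene absent from all strains")
    core = set(presence.index[present_everywhere])
    accessory = set(presence.index[~present_everywhere])
    return core, accessory
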
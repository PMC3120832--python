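"""Reader/writer for the 21-column PSL alignment format.

Coordinates follow the format's conventions: 0-based half-open, qStart/qEnd
always in forward-read coordinates, and the per-block qStarts list in
reverse-complement coordinates for '-' strand alignments (which is also how
:class:`~dpnseq.align.AlignmentRecord` stores blocks internally).
"""

from __future__ import annotations

from pathlib import Path

from .align import AlignmentRecord

HEADER = (
    "matches\tmisMatches\trepMatches\tnCount\tqNumInsert\tqBaseInsert\t"
    "tNumInsert\ttBaseInsert\tstrand\tqName\tqSize\tqStart\tqEnd\ttName\t"
    "tSize\ttStart\ttEnd\tblockCount\tblockSizes\tqStarts\ttStarts"
)


def record_to_psl(rec: AlignmentRecord) -> str:
    q_ins = q_ins_b = t_ins = t_ins_b = 0
    for (q0, t0, l0), (q1, t1, _) in zip(rec.blocks, rec.blocks[1:]):
        qg = q1 - (q0 + l0)
        tg = t1 - (t0 + l0)
        if qg > 0:
            q_ins += 1
            q_ins_b += qg
        if tg > 0:
            t_ins += 1
            t_ins_b += tg
    if rec.strand == "+":
        q_start, q_end = rec.qstart, rec.qend
    else:
        q_start, q_end = rec.qsize - rec.qend, rec.qsize - rec.qstart
    sizes = ",".join(str(l) for _, _, l in rec.blocks) + ","
    qstarts = ",".join(str(q) for q, _, _ in rec.blocks) + ","
    tstarts = ",".join(str(t) for _, t, _ in rec.blocks) + ","
    return "\t".join(
        str(x)
        for x in (
            rec.matches, rec.mismatches, 0, 0, q_ins, q_ins_b, t_ins, t_ins_b,
            rec.strand, rec.read_id, rec.qsize, q_start, q_end, rec.chrom,
            rec.tsize, rec.tstart, rec.tend, len(rec.blocks), sizes, qstarts, tstarts,
        )
    )


def write_psl(records: list[AlignmentRecord], path: str | Path, header: bool = True) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(HEADER + "\n")
        for rec in records:
            fh.write(record_to_psl(rec) + "\n")


def parse_psl_line(line: str) -> AlignmentRecord:
    f = line.rstrip("\n").split("\t")
    if len(f) != 21:
        raise ValueError(f"expected 21 PSL columns, got {len(f)}")
    sizes = [int(x) for x in f[18].rstrip(",").split(",")]
    qstarts = [int(x) for x in f[19].rstrip(",").split(",")]
    tstarts = [int(x) for x in f[20].rstrip(",").split(",")]
    blocks = tuple(zip(qstarts, tstarts, sizes))
    return AlignmentRecord(
        read_id=f[9],
        qsize=int(f[10]),
        chrom=f[13],
        tsize=int(f[14]),
        strand=f[8],
        blocks=blocks,
        matches=int(f[0]),
        mismatches=int(f[1]),
    )


def read_psl(path: str | Path) -> list[AlignmentRecord]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("matches", "psLayout", "-", "#")):
                continue
            try:
                out.append(parse_psl_line(line))
            except ValueError:
                # tolerate the 5-line psLayout preamble emitted by some tools
                continue
    return out
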
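"""Detection of HIC WD40 repeat units in nucleotide gene sequences.

The detector slides a 42-aa window over every forward reading frame of
the input and accepts windows whose mismatch count to the family
consensus, counted at NON-hypervariable positions only, stays within a
budget (default 6 of 35 positions, an ~83% identity floor matching the
high internal conservation of these repeats).  Accepted windows are
chained greedily left-to-right into non-overlapping tandem hits.

A second, rescue pass then inspects the gaps between chained hits: a
gap of roughly one repeat period that aligns to a neighbouring repeat
(or to the reverse-translated consensus) within a nucleotide edit
budget is recovered as a disrupted unit — flagged ``frameshift_suspect``
when its length is not a multiple of 3 or the alignment needs an indel,
and ``has_stop`` when its best-frame translation contains a stop.  This
is what lets stop-codon and single-bp-deletion alleles keep their place
in the repeat architecture instead of silently dropping out.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import edlib
import numpy as np
from Bio.Seq import Seq

from .constants import HET_E_CONSENSUS_AA, HYPERVARIABLE_POSITIONS
from .simulate import reverse_translate

__all__ = [
    "GeneSequence",
    "DetectionParams",
    "RepeatHit",
    "RepeatTrack",
    "detect_repeats",
    "flag_disruptions",
    "extract_haplotype",
    "write_track_tsv",
]


@dataclass(frozen=True)
class GeneSequence:
    id: str
    nt: str
    source: str | None = None

    def __post_init__(self) -> None:
        if not self.nt:
            raise ValueError("empty sequence")
        bad = set(self.nt.upper()) - set("ACGTN")
        if bad:
            raise ValueError(f"sequence contains non-ACGTN symbols: {bad}")


@dataclass(frozen=True)
class DetectionParams:
    consensus_aa: str = HET_E_CONSENSUS_AA
    hypervariable_positions: tuple[int, ...] = HYPERVARIABLE_POSITIONS
    max_mismatch_nonhv: int = 6
    scan_reverse_strand: bool = False
    nt_edit_budget: int = 8
    min_report: int = 1

    def __post_init__(self) -> None:
        n_nonhv = len(self.consensus_aa) - len(self.hypervariable_positions)
        if self.max_mismatch_nonhv > n_nonhv:
            raise ValueError(
                f"max_mismatch_nonhv ({self.max_mismatch_nonhv}) exceeds the "
                f"{n_nonhv} non-hypervariable positions"
            )

    @property
    def period_nt(self) -> int:
        return 3 * len(self.consensus_aa)


@dataclass(frozen=True)
class RepeatHit:
    """One detected repeat unit; start/end are 0-based half-open on the
    input nucleotide sequence."""

    start: int
    end: int
    strand: str
    frame: int
    aa: str
    nt: str
    ordinal: int
    flags: frozenset[str] = frozenset()
    mismatches: int = 0

    def with_flags(self, *new: str) -> "RepeatHit":
        return replace(self, flags=self.flags | set(new))


@dataclass
class RepeatTrack:
    gene_id: str
    hits: list[RepeatHit] = field(default_factory=list)

    @property
    def gap_lengths(self) -> list[int]:
        return [
            self.hits[i + 1].start - self.hits[i].end
            for i in range(len(self.hits) - 1)
        ]

    def barcode_hits(self) -> list[RepeatHit]:
        """Hits contributing to the HIC barcode (partials excluded)."""
        return [h for h in self.hits if "partial" not in h.flags]


def _nonhv_mismatches(window: str, consensus: str, hv0: set[int]) -> int:
    return sum(
        1
        for i, (a, b) in enumerate(zip(window, consensus))
        if i not in hv0 and a != b
    )


def _translate_frame(nt: str, frame: int) -> str:
    sub = nt[frame:]
    sub = sub[: len(sub) - len(sub) % 3]
    return str(Seq(sub).translate())


def _candidate_windows(nt: str, params: DetectionParams) -> list[tuple[int, int, int, str]]:
    """All accepted 42-aa windows as (start_nt, mismatches, frame, aa).

    Vectorized: the translated frame is viewed as a byte array and all
    windows are compared to the consensus at the non-hypervariable
    columns in one shot.
    """
    consensus = params.consensus_aa
    L = len(consensus)
    hv0 = {p - 1 for p in params.hypervariable_positions}
    nonhv = np.array([i for i in range(L) if i not in hv0])
    cons_arr = np.frombuffer(consensus.encode(), dtype=np.uint8)[nonhv]
    out = []
    for frame in range(3):
        aa_seq = _translate_frame(nt, frame)
        if len(aa_seq) < L:
            continue
        arr = np.frombuffer(aa_seq.encode(), dtype=np.uint8)
        windows = np.lib.stride_tricks.sliding_window_view(arr, L)
        mms = (windows[:, nonhv] != cons_arr).sum(axis=1)
        for i in np.flatnonzero(mms <= params.max_mismatch_nonhv):
            out.append(
                (frame + 3 * int(i), int(mms[i]), frame, aa_seq[i : i + L])
            )
    return out


def _chain_windows(cands: list[tuple[int, int, int, str]], period: int) -> list[tuple[int, int, int, str]]:
    """Greedy left-to-right chaining of non-overlapping windows.

    Ties at the same admissible position: fewest non-HV mismatches,
    then lexicographically smaller aa.
    """
    cands = sorted(cands, key=lambda c: (c[0], c[1], c[3]))
    chained: list[tuple[int, int, int, str]] = []
    cursor = 0
    idx, n = 0, len(cands)
    while idx < n:
        if cands[idx][0] < cursor:
            idx += 1
            continue
        # sorted by (start, mm, aa): first candidate at this start wins
        chained.append(cands[idx])
        cursor = cands[idx][0] + period
        idx += 1
    return chained


def _best_frame_translation(nt: str) -> str:
    """Translation of the frame with fewest stops (ties: frame 0 first)."""
    best = None
    for frame in range(3):
        aa = _translate_frame(nt, frame)
        key = (aa.count("*"), frame)
        if best is None or key < best[0]:
            best = (key, aa)
    return best[1]


_N_EQUALITIES = [("N", b) for b in "ACGT"]


def _mask_hypervariable_codons(repeat_nt: str, params: DetectionParams) -> str:
    """Replace hypervariable codons with N so rescue alignment scores
    only the conserved positions (mirrors the Pass-1 mismatch rule)."""
    seq = list(repeat_nt)
    for p in params.hypervariable_positions:
        for i in range(3 * (p - 1), min(3 * p, len(seq))):
            seq[i] = "N"
    return "".join(seq)


def _rescue_in_gap(
    gene_nt: str,
    gap_start: int,
    gap_end: int,
    templates: list[str],
    params: DetectionParams,
) -> RepeatHit | None:
    """Attempt nt-level recovery of one disrupted unit inside a gap."""
    period = params.period_nt
    gap_len = gap_end - gap_start
    if not (0.5 * period <= gap_len <= 1.5 * period):
        return None
    gap_nt = gene_nt[gap_start:gap_end]
    best = None
    for tpl in templates:
        res = edlib.align(
            tpl, gap_nt, mode="HW", task="path", additionalEqualities=_N_EQUALITIES
        )
        if res["editDistance"] < 0 or res["editDistance"] > params.nt_edit_budget:
            continue
        if best is None or res["editDistance"] < best[0]:
            loc = res["locations"][0]
            has_indel = "D" in res["cigar"] or "I" in res["cigar"]
            best = (res["editDistance"], loc, has_indel)
    if best is None:
        return None
    dist, (s, e), has_indel = best
    start, end = gap_start + s, gap_start + e + 1
    hit_nt = gene_nt[start:end]
    flags = set()
    if len(hit_nt) % 3 != 0 or has_indel:
        flags.add("frameshift_suspect")
    aa = _best_frame_translation(hit_nt)
    if "*" in aa:
        flags.add("has_stop")
    return RepeatHit(
        start=start,
        end=end,
        strand="+",
        frame=start % 3,
        aa=aa,
        nt=hit_nt,
        ordinal=-1,
        flags=frozenset(flags),
        mismatches=dist,
    )


def detect_repeats(gene: GeneSequence, params: DetectionParams | None = None) -> RepeatTrack:
    """Two-pass repeat detection; see the module docstring.

    Returns hits ordered by start with 0-based ordinals; an empty track
    is a valid result.  Reverse-strand scanning, when enabled, is run on
    the reverse complement and reported only if the forward scan found
    fewer than ``min_report`` hits (inputs are normally oriented
    haplotypes).
    """
    if params is None:
        params = DetectionParams()
    nt = gene.nt.upper()
    chained = _chain_windows(_candidate_windows(nt, params), params.period_nt)
    strand = "+"
    if params.scan_reverse_strand and len(chained) < params.min_report:
        rc = str(Seq(nt).reverse_complement())
        rev = _chain_windows(_candidate_windows(rc, params), params.period_nt)
        if len(rev) > len(chained):
            nt, chained, strand = rc, rev, "-"

    period = params.period_nt
    hits = [
        RepeatHit(
            start=s,
            end=s + period,
            strand=strand,
            frame=frame,
            aa=aa,
            nt=nt[s : s + period],
            ordinal=-1,
            mismatches=mm,
        )
        for s, mm, frame, aa in chained
    ]

    # Pass 2: rescue disrupted units from inter-hit gaps.  Templates are
    # masked at the hypervariable codons so the edit budget measures
    # only conserved positions and indels.
    templates = [
        _mask_hypervariable_codons(t, params)
        for t in [h.nt for h in hits] + [reverse_translate(params.consensus_aa)]
    ]
    gaps = []
    if hits:
        # terminal windows flanking the outermost hits are scanned too,
        # truncated to 1.5 periods, so a disrupted first or last unit is
        # not lost merely for lacking a second neighbour
        reach = int(1.5 * period)
        gaps.append((max(0, hits[0].start - reach), hits[0].start))
        for a, b in zip(hits, hits[1:]):
            gaps.append((a.end, b.start))
        gaps.append((hits[-1].end, min(len(nt), hits[-1].end + reach)))
    for gap_start, gap_end in gaps:
        rescued = _rescue_in_gap(nt, gap_start, gap_end, templates, params)
        if rescued is not None:
            hits.append(rescued)

    hits.sort(key=lambda h: h.start)
    track = RepeatTrack(
        gene_id=gene.id,
        hits=[replace(h, ordinal=i) for i, h in enumerate(hits)],
    )
    return flag_disruptions(track)


def flag_disruptions(track: RepeatTrack) -> RepeatTrack:
    """Set ``has_stop`` on every hit whose in-frame translation contains
    a stop.  Idempotent; ``frameshift_suspect`` flags from the rescue
    pass are preserved."""
    flagged = []
    for hit in track.hits:
        aa = hit.aa if len(hit.nt) % 3 == 0 else _best_frame_translation(hit.nt)
        if "*" in aa:
            flagged.append(hit.with_flags("has_stop"))
        else:
            flagged.append(hit)
    return RepeatTrack(gene_id=track.gene_id, hits=flagged)


def extract_haplotype(
    assembly: GeneSequence,
    upstream_anchor: str,
    downstream_anchor: str,
    max_anchor_mismatch: int = 2,
) -> GeneSequence:
    """Extract the region between two approximate anchor matches,
    inclusive of the anchors.

    Raises ``ValueError`` when an anchor cannot be located within the
    mismatch budget, or when the anchors are found out of order.
    """
    for name, anchor in (("upstream", upstream_anchor), ("downstream", downstream_anchor)):
        if len(anchor) < 20:
            raise ValueError(f"{name} anchor shorter than 20 nt")
    nt = assembly.nt.upper()

    def locate(anchor: str, name: str) -> tuple[int, int]:
        res = edlib.align(anchor.upper(), nt, mode="HW", task="locations")
        if res["editDistance"] < 0 or res["editDistance"] > max_anchor_mismatch:
            raise ValueError(
                f"{name} anchor not found within {max_anchor_mismatch} edits "
                f"in {assembly.id}"
            )
        s, e = res["locations"][0]
        return s, e + 1

    up = locate(upstream_anchor, "upstream")
    down = locate(downstream_anchor, "downstream")
    if down[0] < up[1]:
        raise ValueError(
            f"anchors out of order in {assembly.id}: downstream match at "
            f"{down[0]} precedes upstream match end {up[1]}"
        )
    return GeneSequence(
        id=f"{assembly.id}:{up[0] + 1}-{down[1]}",
        nt=nt[up[0] : down[1]],
        source=assembly.id,
    )


def write_track_tsv(track: RepeatTrack, path) -> None:
    """Track report with 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        fh.write("gene_id\tordinal\tstart_1based\tend_1based\tstrand\taa\tflags\n")
        for h in track.hits:
            fh.write(
                "\t".join(
                    [
                        track.gene_id,
                        str(h.ordinal),
                        str(h.start + 1),
                        str(h.end),
                        h.strand,
                        h.aa,
                        ";".join(sorted(h.flags)) or ".",
                    ]
                )
                + "\n"
            )
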
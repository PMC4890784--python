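"""Virus discovery from unmapped reads and structural annotation of the
recovered genome.

The assembler is a deliberately simple exact-overlap greedy merger: at desk
scale, with error-free reads, repeatedly joining the pair with the longest
exact suffix-prefix overlap reconstructs a non-repetitive template exactly
(or its reverse complement).  Externally assembled contigs can be supplied
as FASTA instead (see the pipeline layer) — the downstream annotation does
not care where contigs came from.

Layout annotation follows the plus (ORF-encoding) strand: 1-based inclusive
coordinates, ORF end includes the stop codon, frame = ((start - 1) mod 3)
+ 1, 5' UTR = orf1.start - 1, spacer = orf2.start - orf1.end - 1, 3' UTR =
genome length - last ORF end.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Iterable, NamedTuple, Sequence

from .align import AlignmentSet, revcomp
from .errors import ConfigurationError

STOP_CODONS = {"TAA", "TAG", "TGA"}


# --------------------------------------------------------------------------
# Unmapped-read triage


def collect_unmapped(alignment: AlignmentSet, reads: Sequence[str]) -> list[str]:
    """Exactly the reads whose hit list is empty, in input order."""
    if len(alignment.hits) != len(reads):
        raise ConfigurationError(
            f"alignment covers {len(alignment.hits)} reads, got {len(reads)}")
    return [read for read, hits in zip(reads, alignment.hits) if not hits]


# --------------------------------------------------------------------------
# Greedy exact-overlap assembly


@dataclass
class Contig:
    sequence: str
    support: int                       # reads merged into the contig
    assigned_fraction: float | None = None

    def __len__(self) -> int:
        return len(self.sequence)


def _canonical(seq: str) -> str:
    rc = revcomp(seq)
    return seq if seq <= rc else rc


def greedy_assemble(reads: Iterable[str], min_overlap: int = 15,
                    max_rounds: int | None = None) -> list[Contig]:
    """Merge reads by longest exact suffix-prefix overlap until none remains.

    Both orientations are considered; a fully contained sequence is absorbed.
    Ties on overlap length break lexicographically on the (left, right)
    sequence pair, making the output deterministic.  Contigs are returned
    longest-first with their read support.
    """
    if min_overlap < 15:
        raise ConfigurationError(f"min_overlap={min_overlap} below minimum of 15")
    support: Counter = Counter()
    for read in reads:
        support[_canonical(read.upper())] += 1

    seqs: dict[int, str] = {i: s for i, s in enumerate(sorted(support))}
    counts: dict[int, int] = {i: support[s] for i, s in seqs.items()}
    next_id = len(seqs)
    rounds = 0
    while len(seqs) > 1 and (max_rounds is None or rounds < max_rounds):
        rounds += 1
        # prefix index over both orientations of every live sequence
        index: dict[str, list[tuple[int, str]]] = {}
        oriented: dict[tuple[int, str], str] = {}
        for sid in sorted(seqs):
            seq = seqs[sid]
            for orient, s in (("+", seq), ("-", revcomp(seq))):
                oriented[(sid, orient)] = s
                if len(s) >= min_overlap:
                    index.setdefault(s[:min_overlap], []).append((sid, orient))
        maxlen = max(len(s) for s in seqs.values())

        best = None  # (overlap, left_seq, right_seq, left_id, right_id)
        for sid in sorted(seqs):
            for orient in ("+", "-"):
                a = oriented[(sid, orient)]
                best_o = best[0] if best else min_overlap - 1
                for o in range(min(len(a), maxlen), best_o, -1):
                    if o < min_overlap:
                        break
                    key = a[len(a) - o:len(a) - o + min_overlap]
                    found = None
                    for bid, borient in index.get(key, ()):
                        if bid == sid:
                            continue
                        b = oriented[(bid, borient)]
                        if len(b) < o or not b.startswith(a[len(a) - o:]):
                            continue
                        if found is None or b < found[0]:
                            found = (b, bid)
                    if found is not None:
                        cand = (o, a, found[0], sid, found[1])
                        if best is None or (cand[0], ) > (best[0], ) or (
                                cand[0] == best[0] and (cand[1], cand[2]) < (best[1], best[2])):
                            best = cand
                        break  # longest overlap for this (sid, orient) found
        if best is None:
            break
        o, left, right, lid, rid = best
        merged = left if o == len(right) else left + right[o:]
        new_count = counts.pop(lid) + counts.pop(rid)
        del seqs[lid], seqs[rid]
        seqs[next_id] = merged
        counts[next_id] = new_count
        next_id += 1

    contigs = [Contig(seqs[i], counts[i]) for i in seqs]
    contigs.sort(key=lambda c: (-len(c.sequence), c.sequence))
    return contigs


def rank_contigs(contigs: Sequence[Contig], unmapped_reads: Sequence[str],
                 ) -> list[Contig]:
    """Assign each unmapped read to the first contig containing it exactly
    (either orientation) and annotate contigs with assigned-read fractions.

    Contigs are ranked longest-first; a read counts toward one contig only,
    so fractions over all unmapped reads sum to <= 1.
    """
    ranked = sorted(contigs, key=lambda c: (-len(c.sequence), c.sequence))
    total = len(unmapped_reads)
    assigned = [0] * len(ranked)
    read_counts = Counter(r.upper() for r in unmapped_reads)
    for read, mult in read_counts.items():
        rc = revcomp(read)
        for i, contig in enumerate(ranked):
            if read in contig.sequence or rc in contig.sequence:
                assigned[i] += mult
                break
    return [Contig(c.sequence, c.support, assigned[i] / total if total else 0.0)
            for i, c in enumerate(ranked)]


# --------------------------------------------------------------------------
# ORF finding and genome layout


class OrfRecord(NamedTuple):
    start: int        # 1-based inclusive
    end: int          # 1-based inclusive, includes the stop codon
    frame: int        # ((start - 1) mod 3) + 1
    length_nt: int
    length_aa: int    # (length_nt - 3) / 3
    strand: str = "+"


def find_orfs(sequence: str, min_len_nt: int = 60, strand: str = "+",
              ) -> list[OrfRecord]:
    """All maximal ATG..stop ORFs of at least ``min_len_nt`` (incl. stop).

    "Maximal" = the first ATG of each stop-bounded stretch in each frame.
    ``strand`` is '+', '-', or 'both'; minus-strand ORFs are reported in the
    coordinates of the reverse-complemented sequence.
    """
    seq = sequence.upper().replace("U", "T")
    strands = {"+": ["+"], "-": ["-"], "both": ["+", "-"]}.get(strand)
    if strands is None:
        raise ConfigurationError(f"strand must be '+', '-' or 'both', got {strand!r}")
    orfs = []
    for st in strands:
        s = seq if st == "+" else revcomp(seq)
        for frame0 in range(3):
            start_codon = None  # 0-based position of first ATG since last stop
            for pos in range(frame0, len(s) - 2, 3):
                codon = s[pos:pos + 3]
                if codon in STOP_CODONS:
                    if start_codon is not None:
                        length = pos + 3 - start_codon
                        if length >= min_len_nt:
                            orfs.append(OrfRecord(
                                start=start_codon + 1, end=pos + 3,
                                frame=(start_codon % 3) + 1, length_nt=length,
                                length_aa=(length - 3) // 3, strand=st))
                    start_codon = None
                elif codon == "ATG" and start_codon is None:
                    start_codon = pos
    orfs.sort(key=lambda o: (o.strand, o.start))
    return orfs


@dataclass
class VirusLayout:
    """Structural annotation of a (putative) viral plus strand."""

    genome_length: int
    five_prime_utr_nt: int
    three_prime_utr_nt: int
    spacer_nt: int | None            # between ORF1 end and ORF2 start, exclusive
    orfs: list[OrfRecord]
    overlap_flag: bool = False       # ORFs overlap (negative spacer)
    frameshift_candidate: bool = False  # two ORFs in different frames
    slippery_sites: list["SlipperySite"] = field(default_factory=list)


def annotate_layout(sequence: str, orfs: Sequence[OrfRecord]) -> VirusLayout:
    """UTR/spacer arithmetic over the ordered ORFs of a plus strand."""
    if not orfs:
        raise ConfigurationError("layout needs at least one ORF")
    orfs = sorted(orfs, key=lambda o: o.start)
    n = len(sequence)
    spacer = None
    overlap = False
    if len(orfs) >= 2:
        spacer = orfs[1].start - orfs[0].end - 1
        overlap = spacer < 0
    return VirusLayout(
        genome_length=n,
        five_prime_utr_nt=orfs[0].start - 1,
        three_prime_utr_nt=n - orfs[-1].end,
        spacer_nt=spacer,
        orfs=list(orfs),
        overlap_flag=overlap,
        frameshift_candidate=len(orfs) >= 2 and orfs[0].frame != orfs[1].frame,
    )


def select_layout_orfs(orfs: Sequence[OrfRecord], max_orfs: int = 2,
                       ) -> list[OrfRecord]:
    """Pick the genome's principal ORFs: longest-first, non-overlapping,
    at most ``max_orfs``, returned in genomic order.

    Random sequence throws up short spurious ORFs; the principal ORFs of a
    compact viral genome are by far the longest, so length-greedy selection
    recovers them.
    """
    chosen: list[OrfRecord] = []
    for orf in sorted(orfs, key=lambda o: (-o.length_nt, o.start)):
        if len(chosen) >= max_orfs:
            break
        if all(orf.end < c.start or orf.start > c.end for c in chosen):
            chosen.append(orf)
    chosen.sort(key=lambda o: o.start)
    return chosen


def orient_to_coding(sequence: str, min_len_nt: int = 60) -> str:
    """Return the sequence or its reverse complement, whichever strand
    carries the longest ORF (the plus/coding strand of a recovered contig)."""
    fwd = find_orfs(sequence, min_len_nt=min_len_nt)
    rev = find_orfs(revcomp(sequence), min_len_nt=min_len_nt)
    best_fwd = max((o.length_nt for o in fwd), default=0)
    best_rev = max((o.length_nt for o in rev), default=0)
    return sequence if best_fwd >= best_rev else revcomp(sequence)


def annotate_virus(sequence: str, min_orf_len_nt: int = 300, window_nt: int = 21,
                   pattern_rule: Callable[[str], bool] | None = None) -> VirusLayout:
    """Full structural annotation of a putative viral contig.

    Orients the contig to its coding strand, selects the two principal ORFs,
    computes UTR/spacer arithmetic, and scans for a slippery heptamer
    upstream of the first ORF's stop codon.
    """
    seq = orient_to_coding(sequence, min_len_nt=min_orf_len_nt)
    orfs = select_layout_orfs(find_orfs(seq, min_len_nt=min_orf_len_nt))
    layout = annotate_layout(seq, orfs)
    sites, _truncated = find_slippery_site(seq, layout.orfs[0], window_nt=window_nt,
                                           pattern_rule=pattern_rule)
    layout.slippery_sites = sites
    return layout


# --------------------------------------------------------------------------
# -1 frameshift slippery sites


class SlipperySite(NamedTuple):
    sequence: str        # RNA alphabet
    position: int        # 1-based position of the heptamer's first base
    distance_to_stop: int  # bases between heptamer end and stop-codon start


def homopolymeric_tail_rule(heptamer: str) -> bool:
    """Default heuristic: last four bases identical and A or U/T."""
    tail = heptamer[3:]
    return len(set(tail)) == 1 and tail[0] in "ATU"


def canonical_xxxyyyz_rule(heptamer: str) -> bool:
    """Canonical X XXY YYZ slippery pattern (positions 1-3 and 4-6 homopolymeric)."""
    return len(set(heptamer[:3])) == 1 and len(set(heptamer[3:6])) == 1


def find_slippery_site(sequence: str, orf1: OrfRecord, window_nt: int = 21,
                       pattern_rule: Callable[[str], bool] | None = None,
                       ) -> tuple[list[SlipperySite], bool]:
    """Scan the window ending at the last codon before ORF1's stop for
    slippery heptamers.

    Returns ``(sites, truncated)`` where ``truncated`` flags a window that
    ran past the sequence start and was clipped.  Site sequences are
    reported in RNA alphabet with 1-based positions.
    """
    if pattern_rule is None:
        pattern_rule = homopolymeric_tail_rule
    seq = sequence.upper().replace("U", "T")
    stop_start = orf1.end - 2          # 1-based first base of the stop codon
    window_end = stop_start - 1        # last base before the stop
    window_start = window_end - window_nt + 1
    truncated = window_start < 1
    window_start = max(window_start, 1)
    sites = []
    for pos in range(window_start, window_end - 7 + 2):
        heptamer = seq[pos - 1:pos + 6]
        if pattern_rule(heptamer):
            sites.append(SlipperySite(
                sequence=heptamer.replace("T", "U"),
                position=pos,
                distance_to_stop=stop_start - (pos + 6) - 1))
    return sites, truncated
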
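"""Virtual NlaIII tag index over a unigene reference.

A tag-based expression library reads out, for each transcript, the 21-base
fragment anchored at an NlaIII restriction site: the recognition sequence
``CATG`` plus the 17 bases immediately downstream (the MmeI cut distance).
To interpret sequenced tags we pre-compute every such *virtual tag* present
in the reference unigene set and index it by sequence, so that an observed
tag can be resolved to the gene(s) it could have come from — exactly, or
with at most one substitution in the 17-base variable region.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

TAG_LEN = 21
ANCHOR = "CATG"
_VALID = set("ACGTN")
_COMP = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class ReferenceUnigene:
    """One reference transcript: an id and an uppercase DNA sequence."""

    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if not self.sequence:
            raise ValueError("empty reference sequence")
        bad = set(self.sequence) - _VALID
        if bad:
            raise ValueError(
                f"invalid character {sorted(bad)[0]!r} in sequence of {self.gene_id!r}"
            )


@dataclass
class VirtualTag:
    """A 21-base CATG-anchored tag and every reference site producing it.

    ``occurrences`` holds ``(gene_id, strand, offset)`` triples; the offset is
    the 0-based position of the leftmost base of the 21-base window on the
    unigene's + strand, for both strands.
    """

    tag_seq: str
    occurrences: list[tuple[str, str, int]] = field(default_factory=list)

    @property
    def gene_ids(self) -> set[str]:
        return {g for g, _, _ in self.occurrences}


@dataclass
class TagIndex:
    """Map from tag sequence to :class:`VirtualTag` over a whole reference."""

    tags: dict[str, VirtualTag]
    reference_size: int

    @property
    def n_genes_with_tags(self) -> int:
        genes: set[str] = set()
        for vt in self.tags.values():
            genes.update(vt.gene_ids)
        return len(genes)

    def __len__(self) -> int:
        return len(self.tags)


def extract_tags_for_sequence(
    gene_id: str, sequence: str, both_strands: bool = True
) -> list[tuple[str, str, str, int]]:
    """Enumerate every virtual tag of one unigene.

    Scans for ``CATG`` sites with at least 17 downstream bases; windows
    containing ``N`` are skipped (an N can never match a sequenced tag
    bit-exactly). With ``both_strands`` the reverse complement is scanned the
    same way, recording strand ``-`` and the + strand offset of the window's
    leftmost base.

    Returns a list of ``(tag_seq, gene_id, strand, offset)`` tuples.
    """
    if not sequence:
        raise ValueError("empty reference sequence")
    bad = set(sequence) - _VALID
    if bad:
        raise ValueError(f"invalid character {sorted(bad)[0]!r} in sequence")

    out: list[tuple[str, str, str, int]] = []
    L = len(sequence)

    def scan(seq: str, strand: str) -> None:
        start = seq.find(ANCHOR)
        while start != -1:
            window = seq[start : start + TAG_LEN]
            if len(window) == TAG_LEN and "N" not in window:
                if strand == "+":
                    offset = start
                else:
                    offset = L - start - TAG_LEN
                out.append((window, gene_id, strand, offset))
            start = seq.find(ANCHOR, start + 1)

    scan(sequence, "+")
    if both_strands:
        scan(reverse_complement(sequence), "-")
    return out


def build_tag_index(
    reference: Iterable[ReferenceUnigene], both_strands: bool = True
) -> TagIndex:
    """Index every virtual tag of a unigene reference.

    Tags shared by several genes keep all occurrences; the result does not
    depend on the input record order (occurrences are kept sorted).
    """
    tags: dict[str, VirtualTag] = {}
    seen: set[str] = set()
    n = 0
    for rec in reference:
        if rec.gene_id in seen:
            raise ValueError(f"duplicate gene_id {rec.gene_id!r}")
        seen.add(rec.gene_id)
        n += 1
        for tag_seq, gid, strand, offset in extract_tags_for_sequence(
            rec.gene_id, rec.sequence, both_strands=both_strands
        ):
            tags.setdefault(tag_seq, VirtualTag(tag_seq)).occurrences.append(
                (gid, strand, offset)
            )
    for vt in tags.values():
        vt.occurrences.sort()
    return TagIndex(tags=tags, reference_size=n)


@dataclass(frozen=True)
class MatchReport:
    matched_tags: tuple[str, ...]
    gene_ids: frozenset[str]
    match_tier: str  # "exact" | "one_mismatch" | "none"


def _neighbors(tag_seq: str, anchor_strict: bool) -> Iterator[str]:
    """All Hamming-distance-1 variants of a query tag.

    With ``anchor_strict`` only the 17 variable positions are mutated; every
    true tag starts at an NlaIII cut, so a mismatch inside CATG would imply
    the tag was never produced there.
    """
    first = 0 if not anchor_strict else len(ANCHOR)
    for i in range(first, TAG_LEN):
        for b in "ACGT":
            if b != tag_seq[i]:
                yield tag_seq[:i] + b + tag_seq[i + 1 :]


def query_tag(
    index: TagIndex,
    tag_seq: str,
    max_mismatch: int = 1,
    anchor_strict: bool = True,
) -> MatchReport:
    """Resolve one 21-base tag against the index.

    Exact matches pre-empt one-mismatch matches: only when no exact match
    exists is the 1-substitution neighborhood (3×17 variants by default)
    looked up. The report's gene set is the union over all matched virtual
    tags; a tag matching nothing gets tier ``"none"``.
    """
    if len(tag_seq) != TAG_LEN:
        raise ValueError(f"tag must be {TAG_LEN} bases, got {len(tag_seq)}")
    if max_mismatch not in (0, 1):
        raise ValueError("max_mismatch must be 0 or 1")

    if tag_seq in index.tags:
        vt = index.tags[tag_seq]
        return MatchReport((tag_seq,), frozenset(vt.gene_ids), "exact")
    if max_mismatch == 1:
        hits = [v for v in _neighbors(tag_seq, anchor_strict) if v in index.tags]
        if hits:
            genes: set[str] = set()
            for h in hits:
                genes.update(index.tags[h].gene_ids)
            return MatchReport(tuple(sorted(hits)), frozenset(genes), "one_mismatch")
    return MatchReport((), frozenset(), "none")


# ---------------------------------------------------------------------------
# I/O

def read_reference_fasta(path: str | Path) -> list[ReferenceUnigene]:
    """Load unigenes from a (possibly gzipped) FASTA file.

    Only the first whitespace-delimited token of each header is kept as the
    gene id; sequences are uppercased.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return [
            ReferenceUnigene(rec.id, str(rec.seq).upper())
            for rec in SeqIO.parse(fh, "fasta")
        ]


def write_index_tsv(index: TagIndex, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("tag_seq\tn_genes\toccurrences\n")
        for tag_seq in sorted(index.tags):
            vt = index.tags[tag_seq]
            occ = ",".join(f"{g}:{s}:{o}" for g, s, o in vt.occurrences)
            fh.write(f"{tag_seq}\t{len(vt.gene_ids)}\t{occ}\n")
        fh.write(f"#reference_size\t{index.reference_size}\n")


def read_index_tsv(path: str | Path) -> TagIndex:
    tags: dict[str, VirtualTag] = {}
    reference_size = 0
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("tag_seq"):
            raise ValueError("not a tag index TSV")
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#reference_size"):
                reference_size = int(line.split("\t")[1])
                continue
            tag_seq, _, occ = line.split("\t")
            occurrences = []
            for triple in occ.split(","):
                g, s, o = triple.rsplit(":", 2)
                occurrences.append((g, s, int(o)))
            tags[tag_seq] = VirtualTag(tag_seq, occurrences)
    return TagIndex(tags=tags, reference_size=reference_size)
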
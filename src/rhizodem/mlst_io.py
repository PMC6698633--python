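"""Data model and I/O for multilocus sequence typing (MLST) datasets.

An MLST dataset is a set of per-locus nucleotide alignments sharing one
universe of strain identifiers, plus per-strain metadata (sampling site,
country, species label, and an optional genetic-clade label).  This module
provides FASTA/TSV round-trip I/O, locus concatenation, collapsing of
identical concatenated sequences into multilocus haplotypes, and clone
correction (one representative per haplotype per group).

Missing data policy: alignment columns containing ``N`` or ``-`` in any
sequence are excluded ("complete deletion") before distance computations and
haplotype collapsing.  The retained-column mask is exposed so reports can
state exactly which sites were used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

VALID_CHARS = set("ACGTN-")

#: clade labels understood by downstream grouping operations
KNOWN_CLADES = ("CI", "CII", "CIII", "admixed", "unassigned")


class AlignmentError(ValueError):
    """Sequences within a locus do not form a valid alignment."""


class FormatError(ValueError):
    """Malformed input (duplicate ids, bad characters, missing columns)."""


# ---------------------------------------------------------------------------
# core types
# ---------------------------------------------------------------------------

@dataclass
class LocusAlignment:
    """One aligned locus: a mapping from strain id to an equal-length string.

    Parameters
    ----------
    name:
        Locus label (e.g. ``"nodA"``).
    sequences:
        Mapping strain id -> nucleotide string over ``{A,C,G,T,N,-}``;
        insertion order is the canonical strain order.
    coding:
        Whether the locus is protein-coding.
    frame:
        Reading-frame offset (0/1/2) when coding; codon iteration stops at
        the last complete codon.
    boundaries:
        For concatenated alignments, half-open ``(name, start, stop)``
        intervals of each constituent locus (0-based internally).
    """

    name: str
    sequences: dict[str, str]
    coding: bool = False
    frame: int = 0
    boundaries: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequences:
            raise AlignmentError(f"locus {self.name!r}: no sequences")
        self.sequences = {sid: s.upper() for sid, s in self.sequences.items()}
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise AlignmentError(
                f"locus {self.name!r}: unequal sequence lengths {sorted(lengths)}"
            )
        bad = set("".join(self.sequences.values())) - VALID_CHARS
        if bad:
            raise FormatError(f"locus {self.name!r}: invalid characters {sorted(bad)}")
        if self.frame not in (0, 1, 2):
            raise ValueError(f"frame must be 0/1/2, got {self.frame}")

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))

    @property
    def strains(self) -> list[str]:
        return list(self.sequences)

    @property
    def n(self) -> int:
        return len(self.sequences)

    def to_array(self) -> np.ndarray:
        """(n, length) array of single-byte characters."""
        return np.frombuffer(
            "".join(self.sequences.values()).encode(), dtype="S1"
        ).reshape(self.n, self.length)

    def retained_columns(self) -> np.ndarray:
        """Boolean mask of columns free of ``N``/``-`` (complete deletion)."""
        arr = self.to_array()
        keep = ~np.any((arr == b"N") | (arr == b"-"), axis=0)
        return keep

    def masked(self) -> "LocusAlignment":
        """Alignment restricted to retained columns.

        Coding frame is preserved only if no column is dropped; otherwise the
        result is marked non-coding (codon structure is broken).
        """
        keep = self.retained_columns()
        if keep.all():
            return self
        n_dropped = int((~keep).sum())
        logger.info("locus %s: excluding %d column(s) with N/- (complete deletion)",
                    self.name, n_dropped)
        arr = self.to_array()[:, keep]
        seqs = {sid: arr[i].tobytes().decode() for i, sid in enumerate(self.strains)}
        return LocusAlignment(self.name, seqs, coding=False, frame=0)

    def subset(self, strains) -> "LocusAlignment":
        seqs = {sid: self.sequences[sid] for sid in strains}
        return replace(self, sequences=seqs)


@dataclass
class MLSTDataset:
    """Ordered loci over a shared strain universe, with strain metadata.

    ``metadata`` is a DataFrame indexed by strain id with columns
    ``site, country, species, clade``; strains without a metadata row carry
    ``"unassigned"`` in every field.
    """

    loci: list[LocusAlignment]
    metadata: pd.DataFrame | None = None
    clone_corrected: bool = False

    def __post_init__(self) -> None:
        if not self.loci:
            raise ValueError("dataset must contain at least one locus")
        names = [l.name for l in self.loci]
        if len(set(names)) != len(names):
            raise FormatError(f"duplicate locus names: {names}")

    @property
    def locus_names(self) -> list[str]:
        return [l.name for l in self.loci]

    @property
    def strains(self) -> list[str]:
        """Strains present in every locus, in first-locus order."""
        common = set(self.loci[0].strains)
        for loc in self.loci[1:]:
            common &= set(loc.strains)
        return [s for s in self.loci[0].strains if s in common]

    def locus(self, name: str) -> LocusAlignment:
        for loc in self.loci:
            if loc.name == name:
                return loc
        raise KeyError(name)

    def clades(self) -> pd.Series:
        if self.metadata is None or "clade" not in self.metadata.columns:
            raise ValueError("operation requires clade labels in metadata")
        return self.metadata["clade"]

    def subset(self, strains) -> "MLSTDataset":
        strains = list(strains)
        loci = [l.subset(strains) for l in self.loci]
        meta = self.metadata.loc[strains] if self.metadata is not None else None
        return MLSTDataset(loci, meta, clone_corrected=self.clone_corrected)


@dataclass
class HaplotypeTable:
    """Distinct concatenated sequences with counts and member strains.

    Ordered by decreasing count then lexicographic sequence; ``sequences``
    are post-missing-policy concatenations, with locus ``boundaries``
    recorded as half-open offsets into the concatenation.
    """

    sequences: list[str]
    counts: list[int]
    members: list[list[str]]
    boundaries: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if any(c < 1 for c in self.counts):
            raise ValueError("haplotype counts must be >= 1")
        if [len(m) for m in self.members] != list(self.counts):
            raise ValueError("member lists inconsistent with counts")

    @property
    def k(self) -> int:
        return len(self.sequences)

    @property
    def n(self) -> int:
        return int(sum(self.counts))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_loci_fasta(paths, locus_names=None, coding=None) -> MLSTDataset:
    """Read one FASTA file per locus into an :class:`MLSTDataset`.

    Strain ids are the first whitespace-delimited token of each header.
    ``coding`` maps locus name -> (is_coding, frame); unlisted loci default
    to non-coding.
    """
    paths = [str(p) for p in paths]
    if locus_names is None:
        import os
        locus_names = [os.path.splitext(os.path.basename(p))[0] for p in paths]
    if len(locus_names) != len(paths):
        raise ValueError("locus_names must match paths")
    coding = coding or {}
    loci = []
    for path, name in zip(paths, locus_names):
        seqs: dict[str, str] = {}
        for rec in SeqIO.parse(path, "fasta"):
            sid = rec.id
            if sid in seqs:
                raise FormatError(f"{path}: duplicate strain id {sid!r}")
            seqs[sid] = str(rec.seq)
        is_coding, frame = coding.get(name, (False, 0))
        loci.append(LocusAlignment(name, seqs, coding=is_coding, frame=frame))
    return MLSTDataset(loci)


def write_loci_fasta(ds: MLSTDataset, directory, width: int = 70) -> list[str]:
    """Write one FASTA per locus; returns the file paths."""
    import os
    os.makedirs(directory, exist_ok=True)
    out = []
    for loc in ds.loci:
        path = os.path.join(directory, f"{loc.name}.fasta")
        records = [SeqRecord(Seq(s), id=sid, description="")
                   for sid, s in loc.sequences.items()]
        SeqIO.write(records, path, "fasta")
        out.append(path)
    return out


METADATA_COLUMNS = ("site", "country", "species", "clade")


def attach_metadata(ds: MLSTDataset, table) -> MLSTDataset:
    """Join a strain metadata TSV (or DataFrame) onto the dataset.

    The table needs columns ``strain, site, country, species`` and optionally
    ``clade``.  Strains absent from the table are flagged ``"unassigned"``;
    table rows for unknown strains are ignored with a warning.
    """
    if isinstance(table, pd.DataFrame):
        df = table.copy()
    else:
        df = pd.read_csv(table, sep="\t", dtype=str)
    required = {"strain", "site", "country", "species"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"metadata missing columns: {sorted(missing)}")
    if "clade" not in df.columns:
        df["clade"] = "unassigned"
    df = df.set_index("strain")
    strains = ds.strains
    unknown = df.index.difference(strains)
    if len(unknown):
        logger.warning("metadata rows for %d unknown strain(s) ignored", len(unknown))
    meta = df.reindex(strains)[list(METADATA_COLUMNS)].fillna("unassigned")
    n_missing = int((meta["site"] == "unassigned").sum())
    if n_missing:
        logger.info("%d strain(s) without metadata flagged unassigned", n_missing)
    return MLSTDataset(ds.loci, meta, clone_corrected=ds.clone_corrected)


def write_metadata(ds: MLSTDataset, path) -> None:
    if ds.metadata is None:
        raise ValueError("dataset has no metadata")
    ds.metadata.rename_axis("strain").reset_index().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# concatenation, haplotypes, clone correction
# ---------------------------------------------------------------------------

def concatenate(ds: MLSTDataset, locus_subset=None) -> LocusAlignment:
    """Concatenate selected loci over strains present in all of them.

    Strains missing from any selected locus are excluded and logged.
    Locus boundaries in the concatenation are recorded on the result.
    """
    names = list(locus_subset) if locus_subset is not None else ds.locus_names
    if not names:
        raise ValueError("empty locus subset")
    loci = [ds.locus(nm) for nm in names]
    common = set(loci[0].strains)
    for loc in loci[1:]:
        common &= set(loc.strains)
    order = [s for s in loci[0].strains if s in common]
    dropped = set(loci[0].strains) - common
    if dropped:
        logger.info("concatenate: excluding %d strain(s) missing a locus", len(dropped))
    if not order:
        raise AlignmentError("no strain present in every selected locus")
    bounds, offset = [], 0
    for loc in loci:
        bounds.append((loc.name, offset, offset + loc.length))
        offset += loc.length
    seqs = {sid: "".join(loc.sequences[sid] for loc in loci) for sid in order}
    return LocusAlignment("+".join(names), seqs, boundaries=bounds)


def collapse_haplotypes(aln: LocusAlignment, apply_missing_policy: bool = True) -> HaplotypeTable:
    """Collapse identical sequences into haplotypes.

    Identity is exact string equality after the complete-deletion missing
    data policy; ordering is by decreasing count, ties broken by sequence.
    """
    work = aln.masked() if apply_missing_policy else aln
    groups: dict[str, list[str]] = {}
    for sid, seq in work.sequences.items():
        groups.setdefault(seq, []).append(sid)
    items = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    return HaplotypeTable(
        sequences=[s for s, _ in items],
        counts=[len(m) for _, m in items],
        members=[m for _, m in items],
        boundaries=list(work.boundaries),
    )


def clone_correct(ds: MLSTDataset, by: str = "global") -> MLSTDataset:
    """Retain one representative (lowest strain id) of each multilocus
    haplotype per group.

    ``by`` is ``"global"`` or a metadata column (``site``/``country``/
    ``clade``).  Haplotype identity uses the concatenation of all loci under
    the missing-data policy.
    """
    if by != "global":
        if ds.metadata is None or by not in ds.metadata.columns:
            raise KeyError(f"grouping key {by!r} absent from metadata")
    concat = concatenate(ds).masked()
    keep: list[str] = []
    groups: dict[tuple, list[str]] = {}
    for sid, seq in concat.sequences.items():
        g = "all" if by == "global" else ds.metadata.loc[sid, by]
        groups.setdefault((g, seq), []).append(sid)
    for members in groups.values():
        keep.append(min(members))
    keep_order = [s for s in concat.strains if s in set(keep)]
    out = ds.subset(keep_order)
    out.clone_corrected = True
    return out
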
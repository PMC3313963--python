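"""Epitope tables, protein FASTA, and positive/negative nonamer sets.

The positive set for training is the unique 9-mer cores assigned by the
Gibbs sampler.  The negative set is every 9-mer window of the same
source proteins that is *not fully contained* within any known epitope
span — containment, not mere overlap, defines both the negative-window
exclusion and the epitope-level hit rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

from .gibbs import EpitopeRecord
from .matrices import AMINO_ACIDS, CORE_LENGTH, encode_sequence_masked

logger = logging.getLogger(__name__)

EPITOPE_COLUMNS = ("protein_id", "start", "end", "peptide")


@dataclass(frozen=True)
class NonamerWindow:
    """A 9-mer window with its provenance (protein accession, 1-based start)."""

    sequence: str
    protein_id: str
    start: int


@dataclass
class LabeledNonamerSet:
    """Unique positive cores and unique negative windows, kept disjoint.

    Any negative whose sequence coincides with a positive core is removed
    from the negative side so no sequence carries contradictory labels.
    """

    positives: list[str]
    negatives: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        pos_seen: dict[str, None] = {}
        for p in self.positives:
            pos_seen.setdefault(p.upper())
        pos_set = set(pos_seen)
        neg_seen: dict[str, None] = {}
        dropped = 0
        for n in self.negatives:
            s = n.upper()
            if s in pos_set:
                dropped += 1
                continue
            neg_seen.setdefault(s)
        if dropped:
            logger.info("removed %d negative window(s) identical to positive cores", dropped)
        self.positives = list(pos_seen)
        self.negatives = list(neg_seen)

    def __repr__(self) -> str:
        return f"LabeledNonamerSet({len(self.positives)} positives, {len(self.negatives)} negatives)"


def read_fasta(path) -> dict[str, str]:
    """Read a (multi-record, possibly line-wrapped) FASTA into {id: sequence}."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(path, proteins: dict[str, str], width: int = 60) -> None:
    with open(path, "w") as fh:
        for pid, seq in proteins.items():
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_epitope_table(path, min_len: int = 8, max_len: int = 30) -> list[EpitopeRecord]:
    """Read a TSV epitope table into validated records.

    Required columns: protein_id, start, end, peptide (1-based inclusive
    spans); optional column: haplotype.  Rows violating the span/length
    invariants are rejected with line-numbered warnings; a missing column
    raises.  Lines starting with '#' are treated as comments.
    """
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        logger.warning("epitope table %s is empty", path)
        return []
    missing = [c for c in EPITOPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"epitope table {path} is missing column(s): {', '.join(missing)}")
    if df.empty:
        logger.warning("epitope table %s contains no rows", path)
        return []

    records = []
    has_hap = "haplotype" in df.columns
    for idx, row in df.iterrows():
        line_no = idx + 2  # 1-based, after the header line
        try:
            start, end = int(row["start"]), int(row["end"])
            peptide = str(row["peptide"]).strip().upper()
            if start < 1 or end < start:
                raise ValueError(f"malformed span {start}..{end}")
            if not (min_len <= len(peptide) <= max_len):
                raise ValueError(
                    f"peptide length {len(peptide)} outside {min_len}..{max_len}"
                )
            hap = str(row["haplotype"]).strip() if has_hap and pd.notna(row["haplotype"]) else ""
            records.append(
                EpitopeRecord(str(row["protein_id"]).strip(), start, end, peptide, hap)
            )
        except (ValueError, TypeError) as exc:
            logger.warning("rejecting epitope table row at line %d: %s", line_no, exc)
    return records


def write_epitope_table(path, epitopes: list[EpitopeRecord], header_lines=()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("protein_id\tstart\tend\tpeptide\thaplotype\n")
        for e in epitopes:
            fh.write(f"{e.protein_id}\t{e.start}\t{e.end}\t{e.peptide}\t{e.haplotype}\n")


def enumerate_windows(protein_id: str, sequence: str) -> list[NonamerWindow]:
    """All standard-alphabet 9-mer windows of a protein, 1-based starts."""
    seq = sequence.upper()
    codes = encode_sequence_masked(seq)
    out = []
    for k in range(len(seq) - CORE_LENGTH + 1):
        if (codes[k : k + CORE_LENGTH] >= 0).all():
            out.append(NonamerWindow(seq[k : k + CORE_LENGTH], protein_id, k + 1))
    return out


def build_negative_set(
    proteins: dict[str, str], epitopes: list[EpitopeRecord]
) -> list[NonamerWindow]:
    """Negative 9-mers: windows of the source proteins not fully inside any epitope.

    Every 9-mer window [s, s+8] of each protein carrying at least one
    epitope is kept unless some epitope span of that protein fully
    contains it.  Windows with non-standard residues are excluded (and
    counted); the result is deduplicated by sequence, keeping the first
    occurrence's provenance.
    """
    by_protein: dict[str, list[EpitopeRecord]] = {}
    for e in epitopes:
        by_protein.setdefault(e.protein_id, []).append(e)
    missing = sorted(pid for pid in by_protein if pid not in proteins)
    if missing:
        raise ValueError(
            "epitope protein(s) missing from FASTA: " + ", ".join(missing)
        )

    seen: dict[str, NonamerWindow] = {}
    n_contained = n_nonstandard = n_dup = 0
    for pid, eps in by_protein.items():
        seq = proteins[pid]
        spans = [(e.start, e.end) for e in eps]
        n_possible = max(0, len(seq) - CORE_LENGTH + 1)
        windows = enumerate_windows(pid, seq)
        n_nonstandard += n_possible - len(windows)
        for w in windows:
            w_end = w.start + CORE_LENGTH - 1
            if any(s <= w.start and w_end <= e for s, e in spans):
                n_contained += 1
                continue
            if w.sequence in seen:
                n_dup += 1
                continue
            seen[w.sequence] = w
    logger.info(
        "negative set: %d unique windows (%d inside epitopes, %d non-standard, "
        "%d duplicate excluded)",
        len(seen), n_contained, n_nonstandard, n_dup,
    )
    return list(seen.values())


def epitope_hit(epitope: EpitopeRecord, predicted) -> bool:
    """True iff at least one predicted nonamer lies fully inside the epitope.

    ``predicted`` is an iterable of (start, end) spans or objects with a
    ``span`` attribute, 1-based inclusive, on the epitope's protein.
    """
    for p in predicted:
        s, e = p.span if hasattr(p, "span") else (p[0], p[1])
        if epitope.start <= s and e <= epitope.end:
            return True
    return False


def shared_core_count(cores_a, cores_b) -> int:
    """Number of core sequences present in both deduplicated core sets."""
    return len({str(c).upper() for c in cores_a} & {str(c).upper() for c in cores_b})


def shared_epitope_count(epitopes_a, epitopes_b) -> int:
    """Number of distinct epitope peptide sequences shared by two epitope lists."""

    def seqs(eps):
        return {(e.peptide if isinstance(e, EpitopeRecord) else str(e)).upper() for e in eps}

    return len(seqs(epitopes_a) & seqs(epitopes_b))


def position_frequency_table(cores) -> pd.DataFrame:
    """Per-position residue frequencies of a core list (9 rows x 20 columns).

    Rows are core positions 1..9, columns the standard residues; every row
    sums to 1.  This is the table a sequence-logo renderer consumes.
    """
    cores = [str(c).upper() for c in cores]
    if not cores:
        raise ValueError("position_frequency_table requires a non-empty core list")
    counts = np.zeros((CORE_LENGTH, len(AMINO_ACIDS)))
    aa_index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    for core in cores:
        if len(core) != CORE_LENGTH:
            raise ValueError(f"core {core!r} is not a nonamer")
        for pos, aa in enumerate(core):
            counts[pos, aa_index[aa]] += 1
    freq = counts / counts.sum(axis=1, keepdims=True)
    return pd.DataFrame(freq, index=range(1, CORE_LENGTH + 1), columns=list(AMINO_ACIDS))
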
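"""Homopolymer-associated single-base indel error simulation.

Long-read platforms (454, PacBio) make most of their insertion/deletion
errors inside homopolymer runs, and longer runs are more error-prone. The
simulator reproduces that error model: for a transcript of length ``l`` and
error rate ``p`` it plans ``n = round(l * p)`` single-base edits, assigns
them to the ``n`` longest homopolymer runs (ties broken by seeded random
choice, at most one edit per run), and each edit inserts or deletes one
copy of the run's base with probability 1/2 each. Edits therefore never
change base identity outside a run, and the output length differs from the
input by exactly |#insertions - #deletions|.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np

from .errors import InputError
from .io import TranscriptRecord, read_fasta, write_fasta

logger = logging.getLogger(__name__)

_ACGT = set("ACGT")


@dataclass(frozen=True)
class HomopolymerRun:
    """A maximal run of identical bases; start is 1-based, inclusive."""

    base: str
    start: int
    length: int

    @property
    def end(self) -> int:
        """1-based inclusive end position."""
        return self.start + self.length - 1


@dataclass(frozen=True)
class IndelEdit:
    run: HomopolymerRun
    op: Literal["insert", "delete"]


@dataclass(frozen=True)
class IndelPlan:
    """Ordered edit list for one transcript at error rate p."""

    transcript_id: str
    sequence_length: int
    error_rate: float
    n_edits: int
    edits: tuple[IndelEdit, ...] = field(repr=False)
    seed: int = 0


def find_homopolymer_runs(record: TranscriptRecord) -> list[HomopolymerRun]:
    """Decompose a clean ACGT sequence into maximal homopolymer runs.

    Runs tile the sequence left to right without gaps or overlap;
    single-base runs are included so the decomposition is complete.
    """
    seq = record.sequence
    if not seq:
        raise InputError(f"record {record.id!r} has an empty sequence")
    if not _ACGT.issuperset(seq):
        bad = sorted(set(seq) - _ACGT)
        raise InputError(
            f"record {record.id!r} contains non-ACGT characters {bad}; "
            "indels are simulated on clean transcripts only")
    runs: list[HomopolymerRun] = []
    start = 0
    for i in range(1, len(seq) + 1):
        if i == len(seq) or seq[i] != seq[start]:
            runs.append(HomopolymerRun(base=seq[start], start=start + 1,
                                       length=i - start))
            start = i
    return runs


def _edit_count(length: int, p: float, rounding: str) -> int:
    if rounding == "half-up":
        return int(math.floor(length * p + 0.5))
    if rounding == "floor":
        return int(math.floor(length * p))
    raise InputError(f"unknown rounding rule {rounding!r}")


def plan_indels(record: TranscriptRecord, p: float, seed: int = 0,
                rounding: str = "half-up") -> IndelPlan:
    """Plan n = round(l*p) single-base edits on the n longest runs.

    Runs are consumed in strictly decreasing length order; within a length
    class the choice is seeded-uniform. Each selected run receives exactly
    one edit, insert or delete with probability 1/2. If n exceeds the
    number of runs it is capped with a warning.
    """
    if p < 0:
        raise InputError(f"error rate must be non-negative, got {p}")
    runs = find_homopolymer_runs(record)
    n = _edit_count(record.length, p, rounding)
    if n > len(runs):
        logger.warning("record %r: requested %d edits but only %d homopolymer "
                       "runs exist; capping", record.id, n, len(runs))
        n = len(runs)
    rng = np.random.default_rng(seed)
    edits: list[IndelEdit] = []
    if n:
        lengths = np.array([r.length for r in runs])
        # longest-first; ties resolved by a seeded shuffle before the
        # stable sort on negative length
        order = rng.permutation(len(runs))
        order = order[np.argsort(-lengths[order], kind="stable")]
        for idx in order[:n]:
            op = "insert" if rng.random() < 0.5 else "delete"
            edits.append(IndelEdit(run=runs[idx], op=op))
    return IndelPlan(transcript_id=record.id, sequence_length=record.length,
                     error_rate=p, n_edits=len(edits), edits=tuple(edits),
                     seed=seed)


def apply_indels(record: TranscriptRecord, plan: IndelPlan) -> TranscriptRecord:
    """Apply a plan built for this exact sequence.

    Deletions remove one base of the run; insertions add one more copy of
    the run's base inside the run (all positions within a run are
    equivalent because the bases are identical). Edits are applied
    right-to-left so earlier coordinates stay valid.
    """
    if plan.transcript_id != record.id or plan.sequence_length != record.length:
        raise InputError(
            f"plan was built for {plan.transcript_id!r} (l={plan.sequence_length}), "
            f"not {record.id!r} (l={record.length})")
    seq = list(record.sequence)
    for edit in sorted(plan.edits, key=lambda e: e.run.start, reverse=True):
        run = edit.run
        if seq[run.start - 1] != run.base:
            raise InputError(f"plan/sequence mismatch at position {run.start}")
        if edit.op == "delete":
            del seq[run.start - 1]
        else:
            seq.insert(run.start - 1, run.base)
    return TranscriptRecord(id=record.id, sequence="".join(seq))


def simulate_record(record: TranscriptRecord, p: float, seed: int = 0,
                    rounding: str = "half-up") -> tuple[TranscriptRecord, IndelPlan]:
    """Convenience: plan and apply in one step."""
    plan = plan_indels(record, p, seed=seed, rounding=rounding)
    return apply_indels(record, plan), plan


def simulate_fasta(in_path: str | Path, out_path: str | Path, p: float,
                   seed: int = 0, rounding: str = "half-up",
                   log_path: str | Path | None = None) -> list[IndelPlan]:
    """FASTA in, mutated FASTA out; optional per-edit TSV audit log.

    Each record gets an independent stream derived from (seed, record
    index) so results do not depend on how the file is chunked.
    """
    records = read_fasta(in_path)
    out_records: list[TranscriptRecord] = []
    plans: list[IndelPlan] = []
    for i, rec in enumerate(records):
        rec_seed = np.random.SeedSequence([seed, i]).generate_state(1)[0]
        mutated, plan = simulate_record(rec, p, seed=int(rec_seed),
                                        rounding=rounding)
        out_records.append(mutated)
        plans.append(plan)
    write_fasta(out_records, out_path)
    if log_path is not None:
        _write_edit_log(plans, log_path)
    return plans


def _write_edit_log(plans: Iterable[IndelPlan], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["id", "run_start", "run_base", "run_length", "op"])
        for plan in plans:
            for edit in plan.edits:
                writer.writerow([plan.transcript_id, edit.run.start,
                                 edit.run.base, edit.run.length, edit.op])
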
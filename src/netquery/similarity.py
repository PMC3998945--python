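"""Bit-score normalization and E-value-constrained candidate sets.

Each query node may only be aligned to target nodes whose pairwise
sequence-alignment E-value is at most a cutoff E_max; the full pipeline
sweeps the seven cutoffs {0, 1e-100, 1e-50, 1e-10, 1, 10, 100}.  Pairs
absent from the similarity table are forbidden at every cutoff.

Bit scores are normalized to [0, 1] by dividing by the largest raw bit
score in the table.  This keeps the normalization instance-intrinsic and
order-preserving; since the sequence term only breaks ties between
alignments of equal edge correctness, the choice of normalization never
affects the primary topology objective.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field

from netquery.errors import NetQueryError
from netquery.netio import SimilarityTable

#: the E-value cutoff ladder swept by the pipeline, ascending
DEFAULT_CUTOFFS = (0.0, 1e-100, 1e-50, 1e-10, 1.0, 10.0, 100.0)


def default_cutoffs() -> tuple[float, ...]:
    """The seven E-value cutoffs, ascending: (0, 1e-100, 1e-50, 1e-10, 1, 10, 100)."""
    return DEFAULT_CUTOFFS


@dataclass
class CandidateSet:
    """Allowed query → target pairings at a given E-value cutoff.

    ``allowed`` maps each query node to the target nodes with
    E-value <= ``e_max``; ``b`` holds the normalized bit score of every
    allowed pair.  Candidate sets are nested across cutoffs.
    """

    e_max: float
    allowed: dict[str, frozenset[str]] = field(default_factory=dict)
    b: dict[tuple[str, str], float] = field(default_factory=dict)

    def pairs(self) -> list[tuple[str, str]]:
        return sorted(self.b)

    def __len__(self) -> int:
        return len(self.b)

    def is_empty(self) -> bool:
        return not self.b


def normalize_bits(table: SimilarityTable) -> SimilarityTable:
    """Populate ``bits_norm`` by dividing raw bit scores by the global maximum.

    The best-scoring pair(s) get exactly 1.0.  Raises on an empty table or
    all-zero bit scores (no informative similarity signal).
    """
    if not table.entries:
        raise NetQueryError("similarity table is empty")
    max_bits = max(bits for _, bits in table.entries.values())
    if max_bits <= 0.0:
        raise NetQueryError("all bit scores are zero; no informative similarity")
    norm = {pair: bits / max_bits for pair, (_, bits) in table.entries.items()}
    return SimilarityTable(entries=dict(table.entries), bits_norm=norm)


def build_candidates(table: SimilarityTable, e_max: float) -> CandidateSet:
    """Allowed pairs are exactly those with E-value <= e_max (non-strict).

    For ``e_max = 0`` only pairs with E-value exactly zero qualify, which
    BLAST emits when the E-value underflows double precision.
    """
    if e_max < 0:
        raise ValueError(f"e_max must be non-negative, got {e_max}")
    if table.bits_norm is None:
        raise NetQueryError("bit scores not normalized; call normalize_bits first")
    allowed: dict[str, set[str]] = {}
    b: dict[tuple[str, str], float] = {}
    for (q, t), (evalue, _) in table.entries.items():
        if evalue <= e_max:
            allowed.setdefault(q, set()).add(t)
            b[(q, t)] = table.bits_norm[(q, t)]
    return CandidateSet(
        e_max=e_max,
        allowed={q: frozenset(ts) for q, ts in allowed.items()},
        b=b,
    )


# ---------------------------------------------------------------------------
# optional external all-against-all aligner

def blast_executor(query_fasta, target_fasta) -> list[str]:
    """Run blastp all-against-all, yielding tabular (q, s, evalue, bits) lines.

    Requires ``makeblastdb`` and ``blastp`` on PATH.  This is a runtime
    convenience only; the pipeline accepts a precomputed similarity table.
    """
    for tool in ("makeblastdb", "blastp"):
        if shutil.which(tool) is None:
            raise NetQueryError(
                f"{tool} not found on PATH; supply a precomputed similarity table instead"
            )
    with tempfile.TemporaryDirectory() as tmp:
        db = f"{tmp}/targetdb"
        subprocess.run(
            ["makeblastdb", "-in", str(target_fasta), "-dbtype", "prot", "-out", db],
            check=True, capture_output=True,
        )
        proc = subprocess.run(
            ["blastp", "-query", str(query_fasta), "-db", db,
             "-outfmt", "6 qseqid sseqid evalue bitscore"],
            check=True, capture_output=True, text=True,
        )
    return proc.stdout.splitlines()


def run_external_aligner(query_fasta, target_fasta, executor=None) -> SimilarityTable:
    """Produce a SimilarityTable via an external all-against-all protein aligner.

    ``executor`` is a callable (query_fasta, target_fasta) -> iterable of
    tab-separated lines ``query id, subject id, E-value, bit score``; it
    defaults to a local BLAST invocation.  For duplicate hits of the same
    ordered pair the highest bit score is retained.
    """
    if executor is None:
        executor = blast_executor
    try:
        lines = executor(query_fasta, target_fasta)
    except NetQueryError:
        raise
    except Exception as exc:  # nonzero exit, missing binary wrapped by the adapter
        raise NetQueryError(
            f"external aligner failed ({exc}); supply a precomputed similarity table instead"
        ) from exc
    table = SimilarityTable()
    for line in lines:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t") if "\t" in line else line.split()
        if len(cols) < 4:
            raise NetQueryError(f"malformed aligner output line: {line!r}")
        q, t, evalue, bits = cols[0], cols[1], float(cols[2]), float(cols[3])
        prev = table.entries.get((q, t))
        if prev is None or bits > prev[1]:
            table.entries[(q, t)] = (evalue, bits)
    if not table.entries:
        raise NetQueryError("external aligner produced no hits")
    return table
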
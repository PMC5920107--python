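"""Small sequence utilities: point mutations and residue counting.

Used to sanity-check residue inventories (e.g. how many tryptophans a
single-Trp-to-Cys mutant retains) against a user-supplied FASTA of the
parent protein.
"""

from __future__ import annotations

from pathlib import Path

AA1 = set("ACDEFGHIKLMNPQRSTVWY")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Minimal single/multi-record FASTA reader (uppercased sequences)."""
    records: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if name is not None:
                records[name] = "".join(chunks)
            name = line[1:].split()[0]
            chunks = []
        else:
            chunks.append(line.upper())
    if name is not None:
        records[name] = "".join(chunks)
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return records


def apply_mutation(sequence: str, mutation: str) -> str:
    """Apply a point mutation like ``W111C`` (1-based numbering).

    The stated wild-type residue must match the sequence at that position.
    """
    wt, pos, new = mutation[0], int(mutation[1:-1]), mutation[-1]
    if wt not in AA1 or new not in AA1:
        raise ValueError(f"bad mutation spec {mutation!r}")
    if not 1 <= pos <= len(sequence):
        raise ValueError(f"position {pos} outside sequence of length {len(sequence)}")
    if sequence[pos - 1] != wt:
        raise ValueError(
            f"mutation {mutation}: sequence has {sequence[pos - 1]} at {pos}, not {wt}"
        )
    return sequence[:pos - 1] + new + sequence[pos:]


def count_residues(sequence: str, residue: str) -> int:
    """Count occurrences of a one-letter residue type."""
    if residue not in AA1:
        raise ValueError(f"unknown residue code {residue!r}")
    return sequence.count(residue)
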
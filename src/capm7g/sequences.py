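"""Sequence reading, canonicalization and fixed-length window extraction.

Candidate m7G sites are represented as fixed-length RNA windows centered on
a guanosine: by default 250 nt of flank on each side of the candidate base,
giving 501-nt windows. All coordinates are 0-based and point at the
candidate nucleotide itself.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
from Bio import SeqIO

RNA_ALPHABET = "AUCG"
DEFAULT_FLANK = 250

#: row order used by :func:`onehot_encode`
ONEHOT_ROW_ORDER = "AUCG"


class SequenceError(ValueError):
    """Raised for malformed sequences or out-of-range site coordinates."""


@dataclass
class RnaWindow:
    """A validated fixed-length RNA window around a candidate site.

    Attributes
    ----------
    id : str
        Record identifier (FASTA id or synthetic id).
    sequence : str
        Canonical RNA string over {A, U, C, G}.
    label : int or None
        1 = m7G site, 0 = normal site, None = unlabeled query.
    center_index : int
        0-based index of the candidate nucleotide within ``sequence``.
    source : str
        Free-text provenance (file name, generator spec, ...).
    """

    id: str
    sequence: str
    label: Optional[int] = None
    center_index: int = field(default=-1)
    source: str = ""

    def __post_init__(self) -> None:
        if self.center_index < 0:
            self.center_index = len(self.sequence) // 2
        bad = set(self.sequence) - set(RNA_ALPHABET)
        if bad:
            raise SequenceError(
                f"window {self.id!r}: non-AUCG residues {sorted(bad)} "
                "(canonicalize first)"
            )
        if not 0 <= self.center_index < len(self.sequence):
            raise SequenceError(
                f"window {self.id!r}: center_index {self.center_index} outside "
                f"sequence of length {len(self.sequence)}"
            )
        if self.label == 1 and self.sequence[self.center_index] != "G":
            raise SequenceError(
                f"window {self.id!r}: labeled positive but center base is "
                f"{self.sequence[self.center_index]!r}, expected 'G'"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def canonicalize_sequence(
    raw: str,
    *,
    seq_id: str = "<anonymous>",
    ambiguity_policy: str = "reject",
    rng: Optional[np.random.Generator] = None,
) -> str:
    """Uppercase a nucleotide string and map DNA T to RNA U.

    Parameters
    ----------
    ambiguity_policy : {"reject", "random-replace"}
        What to do with residues outside {A, C, G, U, T}: ``reject`` raises
        :class:`SequenceError`; ``random-replace`` substitutes a uniform
        random canonical base drawn from ``rng`` (which is then required).
    """
    if not raw:
        raise SequenceError(f"sequence {seq_id!r}: empty sequence")
    seq = raw.upper().replace("T", "U")
    bad_positions = [i for i, ch in enumerate(seq) if ch not in RNA_ALPHABET]
    if bad_positions:
        if ambiguity_policy == "random-replace":
            if rng is None:
                raise ValueError("random-replace policy requires an rng")
            chars = list(seq)
            for i in bad_positions:
                chars[i] = RNA_ALPHABET[rng.integers(4)]
            warnings.warn(
                f"sequence {seq_id!r}: replaced {len(bad_positions)} ambiguous "
                "residues with random bases"
            )
            return "".join(chars)
        examples = "".join(sorted({seq[i] for i in bad_positions[:5]}))
        raise SequenceError(
            f"sequence {seq_id!r}: {len(bad_positions)} residues outside "
            f"AUCGT (e.g. {examples!r})"
        )
    return seq


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a (optionally gzipped) FASTA file into ordered (id, sequence) pairs.

    Sequences are returned raw (not canonicalized); multi-line bodies are
    concatenated. Empty files and records with empty bodies are errors.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as handle:
        records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(handle, "fasta")]
    if not records:
        raise SequenceError(f"{path}: no FASTA records found")
    for rec_id, seq in records:
        if not seq:
            raise SequenceError(f"{path}: record {rec_id!r} has an empty sequence")
    return records


def read_site_table(path: str | Path) -> list[tuple[str, int, Optional[int]]]:
    """Read a BED-like 3-column TSV: sequence-id, 0-based site, optional label."""
    rows: list[tuple[str, int, Optional[int]]] = []
    for line_no, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise SequenceError(f"{path}:{line_no}: expected >= 2 tab-separated columns")
        label = int(parts[2]) if len(parts) > 2 and parts[2] != "" else None
        rows.append((parts[0], int(parts[1]), label))
    if not rows:
        raise SequenceError(f"{path}: no site rows found")
    return rows


def extract_window(
    sequence: str,
    site: int,
    flank: int = DEFAULT_FLANK,
    *,
    seq_id: str = "<anonymous>",
    label: Optional[int] = None,
    source: str = "",
) -> RnaWindow:
    """Cut a (2*flank + 1)-long window centered on ``site``.

    Sites closer than ``flank`` to either end raise (no padding rule is
    defined for truncated windows); use :func:`extract_windows` to skip
    them with a warning instead.
    """
    if not 0 <= site < len(sequence):
        raise SequenceError(
            f"sequence {seq_id!r}: site {site} outside [0, {len(sequence)})"
        )
    if flank < 0:
        raise ValueError("flank must be >= 0")
    if site < flank or site + flank >= len(sequence):
        raise SequenceError(
            f"sequence {seq_id!r}: site {site} is closer than flank={flank} "
            "to a sequence end (windows are not padded)"
        )
    window_seq = sequence[site - flank : site + flank + 1]
    return RnaWindow(
        id=f"{seq_id}:{site}",
        sequence=canonicalize_sequence(window_seq, seq_id=seq_id),
        label=label,
        center_index=flank,
        source=source or seq_id,
    )


def extract_windows(
    sequence: str,
    sites: Iterable[tuple[int, Optional[int]]],
    flank: int = DEFAULT_FLANK,
    *,
    seq_id: str = "<anonymous>",
) -> list[RnaWindow]:
    """Extract windows for many sites, skipping near-end sites with a warning."""
    out = []
    for site, label in sites:
        try:
            out.append(
                extract_window(sequence, site, flank, seq_id=seq_id, label=label)
            )
        except SequenceError as exc:
            warnings.warn(f"skipping site: {exc}")
    return out


def onehot_encode(window: RnaWindow) -> np.ndarray:
    """One-hot encode a window as a 4 x n binary matrix (row order A, U, C, G)."""
    idx = np.fromiter(
        (ONEHOT_ROW_ORDER.index(ch) for ch in window.sequence),
        dtype=np.intp,
        count=len(window.sequence),
    )
    mat = np.zeros((4, len(window.sequence)), dtype=np.float64)
    mat[idx, np.arange(len(window.sequence))] = 1.0
    return mat
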
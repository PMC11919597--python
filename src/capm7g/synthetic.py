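"""Synthetic motif-planted RNA windows for end-to-end testing.

Emulates the shape of an m7G benchmark set: balanced positive/negative
501-nt windows, every window centered on a G. Positives additionally carry
planted flanking motifs (by default GGG, CU and UC — the patterns enriched
around genuine m7G sites) inserted at seeded positions near the center;
negatives are pure background with a central G. The ONLY discriminative
signal is therefore the motif context, mirroring the biological task of
separating modified from unmodified guanosines.

A ground-truth manifest records every insertion so attribution analyses
can be checked against the planted signal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .sequences import RNA_ALPHABET, RnaWindow

#: per-window insertion counts (GGG, CU, UC) for each signal strength
STRENGTH_PRESETS: dict[str, list[tuple[str, int, tuple[int, int]]]] = {
    "weak": [("GGG", 2, (-100, 100)), ("CU", 1, (-100, 100)), ("UC", 1, (-100, 100))],
    "medium": [("GGG", 6, (-100, 100)), ("CU", 4, (-100, 100)), ("UC", 4, (-100, 100))],
    "strong": [("GGG", 16, (-100, 100)), ("CU", 10, (-100, 100)), ("UC", 10, (-100, 100))],
}

#: roughly human-transcriptome-like base composition (A, U, C, G)
GC_SKEWED_BACKGROUND = (0.24, 0.24, 0.26, 0.26)


@dataclass
class SyntheticSpec:
    """Generator parameters.

    ``motif_set`` entries are (motif, insertions-per-positive-window,
    (lo, hi) start-offset range relative to the center). When None, the
    ``signal_strength`` preset is used; an explicit empty list gives
    zero-signal data (positives and negatives identically distributed
    apart from both having a central G).
    """

    n_per_class: int = 100
    window_length: int = 501
    background_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    motif_set: Optional[list[tuple[str, int, tuple[int, int]]]] = None
    signal_strength: str = "strong"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_length % 2 == 0:
            raise ValueError("window_length must be odd")
        if abs(sum(self.background_probs) - 1.0) > 1e-9:
            raise ValueError("background_probs must sum to 1")
        if self.motif_set is None:
            if self.signal_strength not in STRENGTH_PRESETS:
                raise ValueError(
                    f"signal_strength must be one of {sorted(STRENGTH_PRESETS)}"
                )
            self.motif_set = [tuple(m) for m in STRENGTH_PRESETS[self.signal_strength]]
        for motif, _count, _window in self.motif_set:
            if set(motif) - set(RNA_ALPHABET):
                raise ValueError(f"motif {motif!r} has non-AUCG characters")
            if len(motif) > self.window_length:
                raise ValueError(
                    f"motif {motif!r} longer than window ({self.window_length})"
                )

    def to_dict(self) -> dict:
        return {
            "n_per_class": self.n_per_class,
            "window_length": self.window_length,
            "background_probs": list(self.background_probs),
            "motif_set": [
                [m, c, list(w)] for m, c, w in (self.motif_set or [])
            ],
            "signal_strength": self.signal_strength,
            "seed": self.seed,
        }


def _background(rng: np.random.Generator, n: int, probs) -> list[str]:
    bases = rng.choice(list(RNA_ALPHABET), size=n, p=list(probs))
    return list(bases)


def generate(spec: SyntheticSpec) -> tuple[list[RnaWindow], list[dict]]:
    """Generate balanced labeled windows plus a ground-truth manifest.

    Every window has a forced central G. Positives get in-place motif
    insertions (overwriting background; later insertions win on overlap,
    insertions never overwrite the central base). Deterministic under
    ``spec.seed``. The manifest has one entry per window recording its
    label and every (motif, start) insertion.
    """
    rng = np.random.default_rng(spec.seed)
    center = spec.window_length // 2
    windows: list[RnaWindow] = []
    manifest: list[dict] = []
    for label in (1, 0):
        for i in range(spec.n_per_class):
            chars = _background(rng, spec.window_length, spec.background_probs)
            chars[center] = "G"
            insertions = []
            if label == 1:
                for motif, count, (lo, hi) in spec.motif_set:
                    for _ in range(count):
                        # rejection-sample a start that fits and misses center
                        for _attempt in range(200):
                            off = int(rng.integers(lo, hi + 1))
                            start = center + off
                            if start < 0 or start + len(motif) > spec.window_length:
                                continue
                            if start <= center < start + len(motif):
                                continue
                            break
                        else:
                            raise ValueError(
                                f"cannot place motif {motif!r} within offsets "
                                f"({lo}, {hi}) of a length-{spec.window_length} window"
                            )
                        chars[start : start + len(motif)] = list(motif)
                        insertions.append({"motif": motif, "start": start})
            wid = f"syn_{'pos' if label else 'neg'}_{i:04d}"
            windows.append(
                RnaWindow(
                    id=wid,
                    sequence="".join(chars),
                    label=label,
                    center_index=center,
                    source=f"synthetic:{spec.signal_strength}:seed={spec.seed}",
                )
            )
            manifest.append({"id": wid, "label": label, "insertions": insertions})
    return windows, manifest


def write_fixture_bundle(spec: SyntheticSpec, outdir: str | Path) -> dict[str, Path]:
    """Write pos.fa, neg.fa and manifest.json; byte-stable under the seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    windows, manifest = generate(spec)
    paths = {
        "pos": outdir / "pos.fa",
        "neg": outdir / "neg.fa",
        "manifest": outdir / "manifest.json",
    }
    for key, label in (("pos", 1), ("neg", 0)):
        lines = []
        for w in windows:
            if w.label == label:
                lines.append(f">{w.id}")
                lines.append(w.sequence)
        paths[key].write_text("\n".join(lines) + "\n")
    paths["manifest"].write_text(
        json.dumps({"spec": spec.to_dict(), "windows": manifest}, indent=1,
                   sort_keys=True)
        + "\n"
    )
    return paths
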
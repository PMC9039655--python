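"""Best-hit attribution of reads against a panel of candidate source genomes.

Unmapped reads are the residue of the capture-then-align pipeline: sequence
that was captured but is too diverged to align to the reference. Classifying
each such read by its best local match against an explicit panel (reference
plus candidate donor genomes) reveals where it came from — the hallmark of a
captured-but-unmapped introgression is a much higher donor fraction among
unmapped reads than among mapped ones.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seq import revcomp
from .efficacy import TargetIndex, best_hit_identity

NO_HIT = "NO_HIT"
AMBIGUOUS = "AMBIGUOUS"


@dataclass
class PanelIndex:
    """Pre-built word indexes (both strands) for one panel member."""

    label: str
    forward: TargetIndex
    reverse: TargetIndex


def build_panel(
    panel: dict[str, np.ndarray | dict[str, np.ndarray]], word_size: int = 11
) -> list[PanelIndex]:
    """Index each panel member; multi-chromosome members are concatenated."""
    if not panel:
        raise ValueError("panel must not be empty")
    if len(set(panel)) != len(panel):
        raise ValueError("panel labels must be unique")
    out = []
    for label, seqs in panel.items():
        if isinstance(seqs, dict):
            concat = np.concatenate(list(seqs.values()))
        else:
            concat = seqs
        out.append(
            PanelIndex(
                label,
                TargetIndex(concat, word_size),
                TargetIndex(revcomp(concat), word_size),
            )
        )
    return out


@dataclass
class AttributionTable:
    """Per-read best-hit labels plus the summary fraction per label."""

    table: pd.DataFrame  # read_id, label, best_identity, margin
    summary: pd.DataFrame  # label, n, fraction

    def fraction(self, label: str) -> float:
        row = self.summary[self.summary["label"] == label]
        return float(row["fraction"].iloc[0]) if len(row) else 0.0


def classify_reads(
    reads: dict[str, np.ndarray],
    panel: dict[str, np.ndarray | dict[str, np.ndarray]] | list[PanelIndex],
    min_identity: float = 0.80,
    ambiguity_margin: float = 0.02,
    word_size: int = 11,
    min_cov: float = 0.80,
) -> AttributionTable:
    """Label each read by its best panel hit.

    label = argmax identity if that identity >= ``min_identity``; AMBIGUOUS
    when the top two candidates are within ``ambiguity_margin``; NO_HIT when
    nothing reaches the identity floor.
    """
    indexes = panel if isinstance(panel, list) else build_panel(panel, word_size)
    if not indexes:
        raise ValueError("panel must not be empty")

    rows = []
    for rid, seq in reads.items():
        idents = {}
        for pi in indexes:
            best = best_hit_identity(seq, pi.forward, pi.reverse, min_cov)
            idents[pi.label] = -1.0 if best is None else best
        ranked = sorted(idents.items(), key=lambda kv: -kv[1])
        top_label, top = ranked[0]
        runner = ranked[1][1] if len(ranked) > 1 else -1.0
        margin = top - runner
        if top < min_identity:
            label = NO_HIT
        elif len(ranked) > 1 and margin < ambiguity_margin:
            label = AMBIGUOUS
        else:
            label = top_label
        rows.append((rid, label, top if top >= 0 else np.nan, margin))
    table = pd.DataFrame(rows, columns=["read_id", "label", "best_identity", "margin"])

    labels = [pi.label for pi in indexes] + [AMBIGUOUS, NO_HIT]
    counts = table["label"].value_counts()
    n_total = max(len(table), 1)
    summary = pd.DataFrame(
        {
            "label": labels,
            "n": [int(counts.get(lb, 0)) for lb in labels],
        }
    )
    summary["fraction"] = summary["n"] / n_total
    return AttributionTable(table, summary)
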
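"""Screening of atypical or low-quality spectra before analysis.

Each TIC-normalized spectrum receives an atypicality score ``A``: the
arc length of the intensity trace divided by its maximum,
``A = sum(|I_{i+1} - I_i|) / max(I)``. Noisy or distorted spectra zig-zag
and score high; a clean fingerprint consists of a moderate number of
smooth excursions and scores low. Scores are compared against Tukey
box-plot fences of the collection: above Q3 + 1.5*IQR a spectrum is
flagged for visual review, above Q3 + 3*IQR it is discarded outright.
If the discards leave a species with a single specimen, that specimen is
discarded as well (a species cannot be learned from one specimen).

The score is an explicit re-specification of the screening idea, not a
re-implementation of any particular published screening routine; flagged
spectra are meant to be checked by eye, as in practice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectra import RawSpectrum

__all__ = ["QCReport", "a_score", "screen_spectra"]


@dataclass
class QCReport:
    """Per-spectrum scores and flags plus the fences used."""

    table: pd.DataFrame  # columns: specimen_id, replicate_id, species, a_score, flag
    fence: float         # review fence (Q3 + 1.5 IQR)
    discard_fence: float  # Q3 + 3 IQR

    def excluded(self) -> list[tuple[str, str]]:
        """(specimen_id, replicate_id) pairs flagged 'discard'."""
        bad = self.table[self.table["flag"] == "discard"]
        return list(zip(bad["specimen_id"], bad["replicate_id"]))


def a_score(s: RawSpectrum) -> float:
    """Arc-length atypicality score of a (TIC-normalized) spectrum."""
    peak = float(s.intensities.max())
    if peak == 0:
        raise ValueError("a-score undefined for an all-zero spectrum")
    return float(np.sum(np.abs(np.diff(s.intensities))) / peak)


def screen_spectra(collection: list[RawSpectrum]) -> QCReport:
    """Score a collection and flag atypical spectra.

    Flags: 'keep' (below the review fence), 'review' (above
    Q3 + 1.5*IQR), 'discard' (above Q3 + 3*IQR, or sole surviving
    specimen of its species after discards). Deterministic and
    independent of input order.
    """
    if len(collection) < 5:
        raise ValueError("need at least 5 spectra to compute fences")
    scores = np.array([a_score(s) for s in collection])
    q1, q3 = np.percentile(scores, [25, 75])
    iqr = q3 - q1
    fence = q3 + 1.5 * iqr
    discard_fence = q3 + 3.0 * iqr
    flags = np.where(scores > discard_fence, "discard",
                     np.where(scores > fence, "review", "keep"))
    table = pd.DataFrame({
        "specimen_id": [s.specimen_id for s in collection],
        "replicate_id": [s.replicate_id for s in collection],
        "species": [s.taxon.species if s.taxon else "" for s in collection],
        "a_score": scores,
        "flag": flags,
    })
    # species reduced to one surviving specimen lose that specimen too
    alive = table[table["flag"] != "discard"]
    labelled = alive[alive["species"] != ""]
    per_species = labelled.groupby("species")["specimen_id"].nunique()
    for species in per_species[per_species == 1].index:
        had_discard = ((table["species"] == species)
                       & (table["flag"] == "discard")).any()
        if had_discard:
            table.loc[table["species"] == species, "flag"] = "discard"
    return QCReport(table=table, fence=float(fence),
                    discard_fence=float(discard_fence))
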
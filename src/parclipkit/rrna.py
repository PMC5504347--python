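"""rRNA positional coverage split by transition class, and hotspot calling.

Coverage uses full read footprints per species and 1-based positions.
Contiguous high-coverage regions are reported in interval style
(start-end, e.g. 96-121) with an explicit threshold/merge/width rule,
since only resulting intervals — not a calling rule — are conventional.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .align import TransitionClass
from .annotate import AnnotatedRead
from .references import ReferenceSet

CLASSES = ("d0", "d1TC", "d1other")
_CLASS_COL = {
    TransitionClass.D0: 0,
    TransitionClass.D1TC: 1,
    TransitionClass.D1OTHER: 2,
}


@dataclass
class RrnaProfile:
    """Per-species (length x 3) class coverage plus class composition."""

    coverage: dict[str, np.ndarray]
    composition: pd.DataFrame  # species, class, fraction (NA when no reads)

    def total(self, species: str) -> np.ndarray:
        return self.coverage[species].sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sid, cov in self.coverage.items():
            for p in range(cov.shape[0]):
                rows.append(
                    {
                        "species": sid,
                        "position": p + 1,
                        "d0": cov[p, 0],
                        "d1TC": cov[p, 1],
                        "d1other": cov[p, 2],
                        "total": cov[p].sum(),
                    }
                )
        return pd.DataFrame(rows)


def rrna_coverage(
    reads: Sequence[AnnotatedRead],
    refset: ReferenceSet,
    use_copies: bool = True,
) -> RrnaProfile:
    """Per-position per-class footprint coverage over every rRNA species.

    Input should be pre-filtered by the rRNA rule (d0/d1TC/d1other, >= 15 nt);
    reads of other categories or classes are ignored defensively.
    """
    coverage = {
        s.id: np.zeros((s.length, 3)) for s in refset.by_category("rRNA")
    }
    class_mass = {sid: np.zeros(3) for sid in coverage}
    for r in reads:
        if r.category != "rRNA" or r.ambiguous:
            continue
        col = _CLASS_COL.get(r.transition_class)
        if col is None:
            continue
        w = r.copies if use_copies else 1
        coverage[r.ref_id][r.start - 1 : r.end, col] += w
        class_mass[r.ref_id][col] += w

    rows = []
    for sid, mass in class_mass.items():
        total = mass.sum()
        for ci, cname in enumerate(CLASSES):
            rows.append(
                {
                    "species": sid,
                    "class": cname,
                    "fraction": mass[ci] / total if total > 0 else np.nan,
                }
            )
    return RrnaProfile(coverage=coverage, composition=pd.DataFrame(rows))


def call_hotspots(
    profile: RrnaProfile,
    frac_of_max: float = 0.25,
    merge_gap: int = 5,
    min_width: int = 10,
) -> pd.DataFrame:
    """Threshold-merge-filter hotspot intervals per species.

    Positions with all-class coverage >= frac_of_max * species maximum form
    runs; runs separated by <= merge_gap positions are merged; runs narrower
    than min_width are dropped.  Intervals are 1-based inclusive.
    """
    rows = []
    for sid, cov in profile.coverage.items():
        total = cov.sum(axis=1)
        peak_cov = total.max()
        if peak_cov <= 0:
            continue
        mask = total >= frac_of_max * peak_cov
        idx = np.nonzero(mask)[0]
        if len(idx) == 0:
            continue
        runs: list[list[int]] = [[int(idx[0]), int(idx[0])]]
        for i in idx[1:]:
            if i - runs[-1][1] - 1 <= merge_gap:
                runs[-1][1] = int(i)
            else:
                runs.append([int(i), int(i)])
        for s0, e0 in runs:
            if e0 - s0 + 1 < min_width:
                continue
            seg = total[s0 : e0 + 1]
            rows.append(
                {
                    "species": sid,
                    "start": s0 + 1,
                    "end": e0 + 1,
                    "peak": s0 + int(np.argmax(seg)) + 1,
                    "mean_coverage": float(seg.mean()),
                }
            )
    return pd.DataFrame(rows, columns=["species", "start", "end", "peak", "mean_coverage"])


def plot_profile(profile: RrnaProfile, species: str, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cov = profile.coverage[species]
    fig, ax = plt.subplots(figsize=(9, 3))
    x = np.arange(1, cov.shape[0] + 1)
    bottom = np.zeros(cov.shape[0])
    for ci, cname in enumerate(CLASSES):
        ax.fill_between(x, bottom, bottom + cov[:, ci], label=cname, step="mid")
        bottom += cov[:, ci]
    ax.set_xlabel(f"{species} position (nt)")
    ax.set_ylabel("coverage")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
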
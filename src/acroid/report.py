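"""Summary statistics over assignment results and hit tables.

Mirrors how a barcoding survey is reported: how many queries got an
unambiguous species, the identity level of those assignments (mean with
sample SD, and the count above an identity threshold), the distribution of
top-hit identities, and — the diagnostic for shared haplotypes — how many
distinct species tie at exactly 100% identity per query.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .assign import AssignmentResult, Status
from .similarity import HitTable

__all__ = ["SummaryReport", "summarize_assignments", "hit_distributions",
           "plot_distributions"]

UNDERFLOW_BIN = float("-inf")


@dataclass
class SummaryReport:
    locus_tag: str
    n_queries: int
    n_assigned: int
    n_assigned_ambiguous: int
    n_unassigned: int
    n_no_hits: int
    mean_top_identity_assigned: float | None
    sd_top_identity_assigned: float | None
    n_assigned_identity_gt: dict[float, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "locus_tag": self.locus_tag,
            "n_queries": self.n_queries,
            "n_assigned": self.n_assigned,
            "n_assigned_ambiguous": self.n_assigned_ambiguous,
            "n_unassigned": self.n_unassigned,
            "n_no_hits": self.n_no_hits,
            "mean_top_identity_assigned": self.mean_top_identity_assigned,
            "sd_top_identity_assigned": self.sd_top_identity_assigned,
        }
        for thr, count in sorted(self.n_assigned_identity_gt.items()):
            out[f"n_assigned_identity_gt{thr:g}"] = count
        return out


def summarize_assignments(
    results: Sequence[AssignmentResult],
    thresholds: Iterable[float] = (99.0,),
) -> SummaryReport:
    """Aggregate one locus' assignment results.

    Ambiguous assignments are tallied separately and excluded from the
    identity mean/SD and the threshold counts ("assigned" always means an
    unambiguous species). Identity spread is the sample SD (n-1); both
    moments are None when nothing qualifies. Threshold counts use strict
    inequality ("over 99%" excludes 99.000 exactly).
    """
    results = list(results)
    loci = sorted({r.locus_tag for r in results})
    if len(loci) > 1:
        raise ValueError(f"mixed loci in one summary: {loci}")
    locus = loci[0] if loci else ""

    by_status = {s: 0 for s in Status}
    for r in results:
        by_status[r.status] += 1
    assigned = [r for r in results if r.status is Status.ASSIGNED]
    # sorted so the floating-point sums are permutation-invariant
    idents = sorted(
        r.top_identity for r in assigned if r.top_identity is not None
    )

    mean = sd = None
    if idents:
        mean = sum(idents) / len(idents)
        if len(idents) > 1:
            var = sum((x - mean) ** 2 for x in idents) / (len(idents) - 1)
            sd = math.sqrt(var)
    counts = {
        float(thr): sum(1 for x in idents if x > thr) for thr in thresholds
    }
    return SummaryReport(
        locus_tag=locus,
        n_queries=len(results),
        n_assigned=by_status[Status.ASSIGNED],
        n_assigned_ambiguous=by_status[Status.ASSIGNED_AMBIGUOUS],
        n_unassigned=by_status[Status.UNASSIGNED_TIE],
        n_no_hits=by_status[Status.NO_HITS],
        mean_top_identity_assigned=mean,
        sd_top_identity_assigned=sd,
        n_assigned_identity_gt=counts,
    )


def hit_distributions(
    tables: Sequence[HitTable],
    bin_width: float = 0.5,
    bin_range: tuple[float, float] = (90.0, 100.0),
) -> tuple[dict[float, int], dict[int, int]]:
    """Top-identity histogram and 100%-tie multiplicity histogram.

    Per query: the maximum percent identity falls into half-open bins of
    *bin_width* over *bin_range* (the last bin closes at the top so a
    perfect 100.000 lands in it; identities below the range are collected
    under a -inf underflow key), and the number of distinct species with a
    hit at exactly 100.000% identity gives k in the tie histogram. A query
    with no hits contributes k = 0 and no identity bin, so the tie
    histogram always sums to the number of queries.
    """
    lo, hi = bin_range
    top_hist: dict[float, int] = {}
    tie_hist: dict[int, int] = {}
    for table in tables:
        hits = list(table)
        k = len({h.subject_species.key() for h in hits
                 if h.pct_identity == 100.0})
        tie_hist[k] = tie_hist.get(k, 0) + 1
        if not hits:
            continue
        top = max(h.pct_identity for h in hits)
        if top < lo:
            left = UNDERFLOW_BIN
        else:
            idx = min(int((top - lo) / bin_width), int((hi - lo) / bin_width) - 1)
            left = round(lo + idx * bin_width, 6)
        top_hist[left] = top_hist.get(left, 0) + 1
    return top_hist, tie_hist


def plot_distributions(
    top_hist: dict[float, int],
    tie_hist: dict[int, int],
    out_path: str | Path,
) -> None:  # pragma: no cover - cosmetic output
    """Write the two histograms side by side as an SVG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.5))
    keys = sorted(k for k in top_hist if k != UNDERFLOW_BIN)
    ax1.bar([f"{k:g}" for k in keys], [top_hist[k] for k in keys],
            color="#4878a8")
    ax1.set_xlabel("top-hit identity bin (%)")
    ax1.set_ylabel("queries")
    ax1.tick_params(axis="x", rotation=90, labelsize=7)
    ks = sorted(tie_hist)
    ax2.bar([str(k) for k in ks], [tie_hist[k] for k in ks], color="#a85448")
    ax2.set_xlabel("species tied at 100% identity")
    ax2.set_ylabel("queries")
    fig.tight_layout()
    fig.savefig(out_path, format="svg")
    plt.close(fig)
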
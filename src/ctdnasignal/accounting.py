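"""UpSet-style accounting of which filters removed which variants.

Removed variants are grouped by their exact failed-filter set (the UpSet
"exclusive intersection" convention), so the counts partition the removed
variants: they sum to the removed total, and the marginal count of a
filter equals the sum of exclusive counts of all combinations containing
it. This is how one reads statements like "the pool filter removed 411
variants, 370 shared with other filters and 41 exclusively".
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .filters import FilterVerdict, LABELS
from .variants import VariantKey


class MembershipMatrix:
    """Failed-filter sets of the *removed* variants only."""

    def __init__(self, memberships: Mapping[VariantKey, frozenset[str]]) -> None:
        for key, failed in memberships.items():
            if not failed:
                raise ValueError(f"variant {key} has an empty failed set; only removed "
                                 "variants belong in the membership matrix")
        self._memberships = dict(memberships)

    @property
    def memberships(self) -> dict[VariantKey, frozenset[str]]:
        return dict(self._memberships)

    def __len__(self) -> int:
        return len(self._memberships)

    @property
    def labels(self) -> tuple[str, ...]:
        present = set().union(*self._memberships.values()) if self._memberships else set()
        return tuple(lab for lab in LABELS if lab in present)

    def marginal(self, label: str) -> int:
        """Number of removed variants failing ``label`` (alone or with others)."""
        return sum(1 for failed in self._memberships.values() if label in failed)


def filter_membership(verdicts: Iterable[FilterVerdict]) -> MembershipMatrix:
    """Membership matrix from a verdict list; kept variants are excluded."""
    return MembershipMatrix({v.key: v.failed for v in verdicts if v.failed})


def exclusive_intersection_counts(
    matrix: MembershipMatrix, min_count: int = 15
) -> dict[frozenset[str], int]:
    """Count removed variants by exact failed-filter combination.

    The full map is always returned; ``min_count`` only governs display
    (see :func:`format_upset` / :func:`plot_upset`, which suppress
    combinations below it, mirroring the usual UpSet presentation).
    """
    return dict(Counter(matrix._memberships.values()))


def format_upset(
    counts: Mapping[frozenset[str], int], min_count: int = 15
) -> str:
    """Text rendering of the exclusive-intersection counts (display-filtered)."""
    shown = sorted(
        ((labels, n) for labels, n in counts.items() if n >= min_count),
        key=lambda item: (-item[1], sorted(item[0])),
    )
    lines = [f"{'count':>8}  combination"]
    for labels, n in shown:
        lines.append(f"{n:>8}  " + "+".join(lab for lab in LABELS if lab in labels))
    hidden = sum(1 for n in counts.values() if n < min_count)
    if hidden:
        lines.append(f"({hidden} combination(s) with fewer than {min_count} variants not shown)")
    return "\n".join(lines)


def counts_to_json_obj(counts: Mapping[frozenset[str], int]) -> list[dict]:
    """Serialize the full map as a list of {labels, count} objects."""
    return [
        {"labels": [lab for lab in LABELS if lab in labels], "count": n}
        for labels, n in sorted(counts.items(), key=lambda kv: (-kv[1], sorted(kv[0])))
    ]


def plot_upset(
    counts: Mapping[frozenset[str], int],
    min_count: int = 15,
    path=None,
    ax=None,
):
    """Minimal UpSet-style plot: intersection bars over a membership dot grid.

    Convenience output only; combinations below ``min_count`` are hidden.
    """
    import matplotlib
    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    shown = sorted(
        ((labels, n) for labels, n in counts.items() if n >= min_count),
        key=lambda item: -item[1],
    )
    labels_present = [lab for lab in LABELS if any(lab in c for c, _ in shown)]
    if ax is None:
        fig, (ax_bar, ax_dot) = plt.subplots(
            2, 1, figsize=(max(4, 0.6 * len(shown) + 2), 5),
            sharex=True, height_ratios=[3, 1.5],
        )
    else:
        ax_bar, ax_dot = ax

    xs = range(len(shown))
    ax_bar.bar(xs, [n for _, n in shown], color="0.25")
    for x, (_, n) in zip(xs, shown):
        ax_bar.text(x, n, str(n), ha="center", va="bottom", fontsize=8)
    ax_bar.set_ylabel("removed variants")
    ax_bar.set_xticks([])

    for x, (combo, _) in zip(xs, shown):
        for y, lab in enumerate(labels_present):
            on = lab in combo
            ax_dot.scatter(x, y, s=40, c="0.2" if on else "0.85", zorder=3)
        ys = [labels_present.index(lab) for lab in combo if lab in labels_present]
        if len(ys) > 1:
            ax_dot.plot([x, x], [min(ys), max(ys)], c="0.2", lw=1.5, zorder=2)
    ax_dot.set_yticks(range(len(labels_present)), labels_present)
    ax_dot.set_ylim(-0.5, len(labels_present) - 0.5)
    ax_dot.invert_yaxis()
    ax_dot.set_xticks([])
    fig = ax_bar.figure
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
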
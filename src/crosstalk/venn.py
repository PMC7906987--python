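"""Partition two DEG sets into unique and overlapping subsets."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass
class VennPartition:
    unique_a: set
    unique_b: set
    shared: set
    labels: tuple[str, str] = ("A", "B")

    def counts(self) -> dict[str, int]:
        a, b = self.labels
        return {
            f"unique_{a}": len(self.unique_a),
            f"unique_{b}": len(self.unique_b),
            "shared": len(self.shared),
        }


def venn_partition(set_a, set_b, labels: tuple[str, str] = ("A", "B")) -> VennPartition:
    """Exact set algebra: (A \\ B, B \\ A, A & B). Empty inputs allowed."""
    a, b = set(set_a), set(set_b)
    return VennPartition(unique_a=a - b, unique_b=b - a, shared=a & b, labels=labels)


def venn_partition_directional(calls_a, calls_b, labels=("A", "B")) -> VennPartition:
    """Direction-aware variant: a gene is shared only when called in both
    sets with the same sign.  ``calls_a``/``calls_b`` map gene -> direction
    (+1/-1).  Genes called in both with opposite signs count as unique on
    both sides.
    """
    a, b = dict(calls_a), dict(calls_b)
    shared = {g for g in set(a) & set(b) if a[g] == b[g]}
    return VennPartition(unique_a=set(a) - shared, unique_b=set(b) - shared,
                         shared=shared, labels=labels)
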
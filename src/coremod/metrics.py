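"""Recovery metrics for benchmarking predicted modules against truth."""

from __future__ import annotations

from typing import Iterable, Mapping

from sklearn.metrics import adjusted_rand_score

__all__ = ["partition_ari", "module_f1", "recovered_fraction"]


def partition_ari(truth: Mapping[str, int], pred: Mapping[str, int]) -> float:
    """Adjusted Rand index between two node -> label partitions."""
    nodes = sorted(set(truth) & set(pred))
    if not nodes:
        raise ValueError("partitions share no nodes")
    return float(adjusted_rand_score([truth[v] for v in nodes],
                                     [pred[v] for v in nodes]))


def module_f1(true_module: Iterable[str], predicted: Iterable[str]) -> float:
    """Set-overlap F1 between a true module and one prediction."""
    t, p = set(true_module), set(predicted)
    if not t or not p:
        return 0.0
    tp = len(t & p)
    if tp == 0:
        return 0.0
    precision = tp / len(p)
    recall = tp / len(t)
    return 2 * precision * recall / (precision + recall)


def recovered_fraction(truth_modules: Iterable[Iterable[str]],
                       predicted_modules: Iterable[Iterable[str]],
                       f1_threshold: float = 0.8) -> float:
    """Fraction of truth modules matched by some prediction at F1 >= threshold."""
    truth_modules = [set(m) for m in truth_modules]
    predicted_modules = [set(m) for m in predicted_modules]
    if not truth_modules:
        raise ValueError("no truth modules")
    hits = sum(
        1 for t in truth_modules
        if predicted_modules and max(module_f1(t, p) for p in predicted_modules)
        >= f1_threshold
    )
    return hits / len(truth_modules)
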
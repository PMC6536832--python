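"""Independent brute-force oracles used only by the test suite.

Each oracle recomputes a quantity by the most direct method available —
explicit loops, naive recursion, flood fill — deliberately sharing no code
with the implementation it checks.
"""

from __future__ import annotations

import numpy as np


def levenshtein_recursive(a: str, b: str) -> int:
    """Exponential-time textbook recursion; only for short strings."""
    if not a:
        return len(b)
    if not b:
        return len(a)
    cost = 0 if a[-1] == b[-1] else 1
    return min(
        levenshtein_recursive(a[:-1], b) + 1,
        levenshtein_recursive(a, b[:-1]) + 1,
        levenshtein_recursive(a[:-1], b[:-1]) + cost,
    )


def confusion_loops(truth: np.ndarray, pred: np.ndarray, n_cl: int) -> np.ndarray:
    """Per-pixel double loop confusion matrix."""
    n = np.zeros((n_cl, n_cl), dtype=np.int64)
    h, w = truth.shape
    for r in range(h):
        for c in range(w):
            n[truth[r, c], pred[r, c]] += 1
    return n


def measures_loops(n: np.ndarray) -> dict[str, float]:
    """The four measures from explicit per-class loops.

    Convention: classes absent from both truth and prediction are skipped
    in the unweighted means; classes predicted but never true contribute
    IU 0 to mean IU.
    """
    n_cl = len(n)
    t = [sum(n[i][j] for j in range(n_cl)) for i in range(n_cl)]
    col = [sum(n[i][j] for i in range(n_cl)) for j in range(n_cl)]
    total = sum(t)

    pa = sum(n[i][i] for i in range(n_cl)) / total

    recalls = [n[i][i] / t[i] for i in range(n_cl) if t[i] > 0]
    ma = sum(recalls) / len(recalls)

    ius = []
    fw = 0.0
    for i in range(n_cl):
        union = t[i] + col[i] - n[i][i]
        if union == 0:
            continue
        iu = n[i][i] / union
        ius.append(iu)
        fw += t[i] * iu
    return {
        "pixel_accuracy": pa,
        "mean_accuracy": ma,
        "mean_iu": sum(ius) / len(ius),
        "freq_weighted_iu": fw / total,
    }


def flood_fill_regions(mask: np.ndarray) -> list[tuple[int, int]]:
    """(class, pixel_count) per 4-connected non-background region, by BFS."""
    h, w = mask.shape
    seen = np.zeros((h, w), dtype=bool)
    out = []
    for r in range(h):
        for c in range(w):
            if seen[r, c] or mask[r, c] == 0:
                continue
            cls = mask[r, c]
            stack = [(r, c)]
            seen[r, c] = True
            count = 0
            while stack:
                y, x = stack.pop()
                count += 1
                for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    ny, nx = y + dy, x + dx
                    if 0 <= ny < h and 0 <= nx < w and not seen[ny, nx] and mask[ny, nx] == cls:
                        seen[ny, nx] = True
                        stack.append((ny, nx))
            out.append((int(cls), count))
    return out
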
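"""Independent brute-force oracles shared by the test modules."""

import numpy as np


def flood_fill_extents(mask: np.ndarray, connectivity: int) -> list[int]:
    """Connected-component extents by explicit stack-based flood fill."""
    offsets = []
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            for dk in (-1, 0, 1):
                if (di, dj, dk) == (0, 0, 0):
                    continue
                dist = abs(di) + abs(dj) + abs(dk)
                if connectivity == 6 and dist > 1:
                    continue
                if connectivity == 18 and dist > 2:
                    continue
                offsets.append((di, dj, dk))
    seen = np.zeros_like(mask, dtype=bool)
    extents = []
    for start in np.argwhere(mask):
        start = tuple(start)
        if seen[start]:
            continue
        stack, size = [start], 0
        seen[start] = True
        while stack:
            i, j, k = stack.pop()
            size += 1
            for di, dj, dk in offsets:
                ni, nj, nk = i + di, j + dj, k + dk
                if (
                    0 <= ni < mask.shape[0]
                    and 0 <= nj < mask.shape[1]
                    and 0 <= nk < mask.shape[2]
                    and mask[ni, nj, nk]
                    and not seen[ni, nj, nk]
                ):
                    seen[ni, nj, nk] = True
                    stack.append((ni, nj, nk))
        extents.append(size)
    return sorted(extents)


def spearman_oracle(x, y) -> float:
    """Spearman rho from first principles: average ranks, then Pearson."""

    def ranks(v):
        order = np.argsort(v, kind="stable")
        r = np.empty(len(v))
        sv = v[order]
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and sv[j + 1] == sv[i]:
                j += 1
            r[order[i : j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return r

    rx, ry = ranks(np.asarray(x, float)), ranks(np.asarray(y, float))
    rx -= rx.mean()
    ry -= ry.mean()
    return float(np.sum(rx * ry) / np.sqrt(np.sum(rx**2) * np.sum(ry**2)))


def bh_stepup_oracle(p):
    """Benjamini-Hochberg adjusted p-values applied literally step by step."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj
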
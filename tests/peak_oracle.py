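"""Independent brute-force oracles for peak geometry and the Wilson interval.

These re-derive the same conventions as the package by exhaustive O(n^2)
scanning with plain Python loops, sharing no code with the implementation.
The width interpolation uses the same algebraic expression so that agreement
can be asserted in exact floating point.
"""

import math

from scipy.stats import norm


def brute_force_peaks(hours, values, noise_floor=5.0, rel_height=0.5):
    """All strict local maxima with (apex_index, height, width).

    Height is apex minus the deeper flanking local minimum; width is the
    horizontal distance between the linear-interpolated crossings of
    ``apex - rel_height*height``, each flank bounded by its neighboring
    minimum (clipped at the minimum when the level is not reached).
    """
    v = list(values)
    t = list(hours)
    n = len(v)
    out = []
    for i in range(n):
        for j in range(i, n):
            if any(v[x] != v[i] for x in range(i, j + 1)):
                break
            if not (i > 0 and j < n - 1 and v[i - 1] < v[i] and v[j + 1] < v[j]):
                continue
            apex = (i + j) // 2
            # left neighboring minimum: smallest k with v non-decreasing on [k, i]
            k = i
            for cand in range(i - 1, -1, -1):
                if all(v[x] <= v[x + 1] for x in range(cand, i)):
                    k = cand
                else:
                    break
            # right neighboring minimum
            m = j
            for cand in range(j + 1, n):
                if all(v[x] >= v[x + 1] for x in range(j, cand)):
                    m = cand
                else:
                    break
            height = v[apex] - min(v[k], v[m])
            if height < noise_floor:
                continue
            level = v[apex] - rel_height * height
            left_candidates = [x for x in range(k, i) if v[x] <= level]
            if left_candidates:
                x = max(left_candidates)
                t_left = t[x + 1] - (v[x + 1] - level) / (v[x + 1] - v[x]) * (t[x + 1] - t[x])
            else:
                t_left = t[k]
            right_candidates = [x for x in range(j + 1, m + 1) if v[x] <= level]
            if right_candidates:
                x = min(right_candidates)
                t_right = t[x - 1] + (v[x - 1] - level) / (v[x - 1] - v[x]) * (t[x] - t[x - 1])
            else:
                t_right = t[m]
            out.append((apex, height, t_right - t_left))
    return out


def wilson_closed_form(k, n, conf=0.95):
    """Textbook Wilson score bounds evaluated longhand."""
    z = norm.ppf(1 - (1 - conf) / 2)
    p = k / n
    denom = 1 + z * z / n
    center = (p + z * z / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return center - half, center + half
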
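"""Independent brute-force reference implementations used by the tests.

These are deliberately naive (per-record Python loops) and stay
independent of the library code paths they check.
"""

from __future__ import annotations

import math
from collections import defaultdict


def brute_crts(records, mbp):
    """Reference CRT construction by explicit per-animal scanning.

    ``records`` is an iterable of ``(receiver, animal, time)`` already
    in canonical order (per animal, time-ascending, ties in record
    order).  Splits at every receiver switch, then splits same-receiver
    runs at gaps strictly larger than ``mbp``.  Returns a list of
    ``(animal, receiver, start, end, n_detections)`` tuples in order.
    """
    per_animal = defaultdict(list)
    for receiver, animal, time in records:
        per_animal[animal].append((receiver, time))

    out = []
    for animal, dets in per_animal.items():
        # split at receiver switches
        runs = []
        for receiver, time in dets:
            if runs and runs[-1][0] == receiver:
                runs[-1][1].append(time)
            else:
                runs.append((receiver, [time]))
        # split runs at gaps > mbp
        for receiver, times in runs:
            current = [times[0]]
            for t in times[1:]:
                if t - current[-1] > mbp:
                    out.append((animal, receiver, current[0], current[-1], len(current)))
                    current = [t]
                else:
                    current.append(t)
            out.append((animal, receiver, current[0], current[-1], len(current)))
    return out


def brute_survival(durations, t):
    """Fraction of durations strictly larger than ``t``."""
    return sum(1 for d in durations if d > t) / len(durations)


def brute_interpolate_at(times, survival, g, t_max):
    """Two-point linear interpolation of one grid point, or None.

    ``None`` marks an undefined point: ``g`` beyond the last raw point,
    or inside a raw span wider than ``t_max``.
    """
    for k in range(len(times)):
        if math.isclose(times[k], g) or times[k] == g:
            return survival[k]
    for k in range(len(times) - 1):
        if times[k] < g < times[k + 1]:
            if times[k + 1] - times[k] > t_max:
                return None
            w = (g - times[k]) / (times[k + 1] - times[k])
            return survival[k] + w * (survival[k + 1] - survival[k])
    return None


def brute_rssr(a_values, a_defined, b_values, b_defined):
    """Accumulate the mean squared difference over jointly defined points."""
    total, count = 0.0, 0
    for av, ad, bv, bd in zip(a_values, a_defined, b_values, b_defined):
        if ad and bd:
            total += (av - bv) ** 2
            count += 1
    if count == 0:
        return None, 0
    return total / count, count
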
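"""Vectorized splitting of at-risk windows into constant-hazard segments.

A person is at risk on the half-open window ``[entry, exit)``.  Within that
window both the baseline rate (piecewise constant in attained age) and the
lagged cumulative dose (a step function jumping at ``exam_age + lag``) are
step functions, so the product hazard is constant on segments delimited by
age-band boundaries and dose-step ages.  Both the outcome simulator and the
person-year tabulator consume this decomposition; building it once, as flat
arrays, keeps each at numpy speed for cohorts of hundreds of thousands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Segments", "split_persontime"]


@dataclass
class Segments:
    """Flat constant-hazard segments over all persons.

    Sorted by (person, t0).  ``z`` is the lagged cumulative dose in force on
    the segment; ``band`` indexes the attained-age band of ``t0``.
    """

    person: np.ndarray    # int index into the caller's person order
    t0: np.ndarray
    t1: np.ndarray
    z: np.ndarray
    band: np.ndarray

    def __len__(self) -> int:
        return len(self.t0)

    @property
    def length(self) -> np.ndarray:
        return self.t1 - self.t0


def split_persontime(entry: np.ndarray, exit_age: np.ndarray,
                     step_person: np.ndarray, step_age: np.ndarray,
                     step_dose: np.ndarray, z_entry: np.ndarray,
                     band_bounds: np.ndarray) -> Segments:
    """Split every person's [entry, exit) window at dose steps and band bounds.

    Parameters
    ----------
    entry, exit_age : per-person window; persons with exit <= entry yield no
        segments.
    step_person, step_age, step_dose : flat dose-step events (already lagged
        ages).  Steps outside the open interval (entry, exit) are ignored;
        steps at or before entry must already be folded into ``z_entry``.
    z_entry : per-person cumulative lagged dose in force at entry.
    band_bounds : increasing attained-age band edges; the first edge must not
        exceed any entry and the last must exceed every exit.

    Raises
    ------
    ValueError if a person's window extends beyond the last band edge.
    """
    n = len(entry)
    entry = np.asarray(entry, float)
    exit_age = np.asarray(exit_age, float)
    bounds = np.asarray(band_bounds, float)
    active = exit_age > entry
    if (exit_age[active] > bounds[-1]).any():
        bad = exit_age[active].max()
        raise ValueError(f"attained age {bad:.3f} beyond last band edge "
                         f"{bounds[-1]:.3f}")
    if len(bounds) and (entry[active] < bounds[0]).any():
        raise ValueError("entry age below first band edge")

    # --- candidate breakpoints: entry, interior dose steps, interior band
    # edges, exit (sentinel).  Inactive persons contribute nothing.
    act_idx = np.flatnonzero(active)
    P_parts = [act_idx, act_idx]
    T_parts = [entry[active], exit_age[active]]
    D_parts = [np.zeros(active.sum()), np.zeros(active.sum())]

    if len(step_age):
        sp = np.asarray(step_person)
        sa = np.asarray(step_age, float)
        sd = np.asarray(step_dose, float)
        keep = active[sp] & (sa > entry[sp]) & (sa < exit_age[sp])
        P_parts.append(sp[keep])
        T_parts.append(sa[keep])
        D_parts.append(sd[keep])

    # interior band edges strictly inside each active window
    lo = np.searchsorted(bounds, entry, side="right")
    hi = np.searchsorted(bounds, exit_age, side="left")
    counts = np.where(active, np.maximum(hi - lo, 0), 0)
    if counts.sum():
        rep_person = np.repeat(np.arange(n), counts)
        # per-person running index 0..count-1
        csum = np.concatenate([[0], np.cumsum(counts)])
        within = np.arange(counts.sum()) - np.repeat(csum[:-1], counts)
        edge_idx = np.repeat(lo, counts) + within
        P_parts.append(rep_person)
        T_parts.append(bounds[edge_idx])
        D_parts.append(np.zeros(counts.sum()))

    P = np.concatenate(P_parts)
    T = np.concatenate(T_parts)
    D = np.concatenate(D_parts)

    order = np.lexsort((T, P))
    P, T, D = P[order], T[order], D[order]

    # grouped cumulative dose: cumsum reset at each person's first row
    cs = np.cumsum(D)
    first = np.flatnonzero(np.r_[True, P[1:] != P[:-1]])
    base = np.repeat(cs[first] - D[first], np.diff(np.r_[first, len(P)]))
    z_run = cs - base + z_entry[P]

    # consecutive rows of the same person delimit segments
    same = P[:-1] == P[1:]
    t0 = T[:-1][same]
    t1 = T[1:][same]
    person = P[:-1][same]
    z = z_run[:-1][same]
    nonzero = t1 > t0
    t0, t1, person, z = t0[nonzero], t1[nonzero], person[nonzero], z[nonzero]
    band = np.searchsorted(bounds, t0, side="right") - 1
    return Segments(person=person, t0=t0, t1=t1, z=z, band=band)
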
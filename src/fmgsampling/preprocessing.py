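"""Range normalization of raw FMG recordings onto a common [0, 1] scale.

Raw FMG readings carry participant- and strap-level bias (physique, strap
tightness, per-channel sensor gain).  Normalization subtracts the minimum and
divides by the full range over a configurable *scope*:

``per_participant_placement`` (default)
    all trials and all channels of one participant's one strap pooled —
    removes participant/strap bias while preserving relative channel
    amplitudes within the strap;
``per_channel``
    per (participant, placement, channel), pooled across trials;
``per_trial``
    each recording on its own, channels pooled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import FMGRecording

SCOPES = ("per_participant_placement", "per_channel", "per_trial")


@dataclass(frozen=True)
class NormalizedRecording(FMGRecording):
    """An FMGRecording mapped onto [0, 1], with normalization provenance.

    ``norm_min`` / ``norm_range`` are scalars, or per-channel arrays for the
    ``per_channel`` scope.
    """

    norm_min: np.ndarray | float = 0.0
    norm_range: np.ndarray | float = 1.0
    scope: str = "per_participant_placement"


def _degenerate(scope: str, key) -> ValueError:
    return ValueError(
        f"zero amplitude range within scope {scope!r} for {key}: "
        "a constant signal cannot be range-normalized"
    )


def normalize(
    recordings: list[FMGRecording],
    scope: str = "per_participant_placement",
) -> list[NormalizedRecording]:
    """Map recordings to [0, 1] via (x - min) / (max - min) over the scope.

    Within each scope the minimum maps to exactly 0 and the maximum to
    exactly 1.  Raises ``ValueError`` for an empty input, an unknown scope,
    or a zero range within any scope (degenerate input).
    """
    if scope not in SCOPES:
        raise ValueError(f"scope must be one of {SCOPES}, got {scope!r}")
    if not recordings:
        raise ValueError("normalize requires at least one recording")

    out: list[NormalizedRecording] = []

    if scope == "per_trial":
        for rec in recordings:
            lo = float(rec.signal.min())
            hi = float(rec.signal.max())
            rng = hi - lo
            if rng <= 0:
                raise _degenerate(
                    scope, f"participant {rec.participant} {rec.action} "
                    f"trial {rec.trial} ({rec.placement})"
                )
            out.append(_build(rec, lo, rng, scope))
        return out

    # Pool trials per (participant, placement).
    groups: dict[tuple, list[FMGRecording]] = {}
    for rec in recordings:
        groups.setdefault((rec.participant, rec.placement), []).append(rec)

    for key, recs in groups.items():
        stack = [r.signal for r in recs]
        if scope == "per_participant_placement":
            lo = float(min(s.min() for s in stack))
            hi = float(max(s.max() for s in stack))
            rng = hi - lo
            if rng <= 0:
                raise _degenerate(scope, f"participant {key[0]} ({key[1]})")
        else:  # per_channel
            lo = np.min([s.min(axis=0) for s in stack], axis=0)
            hi = np.max([s.max(axis=0) for s in stack], axis=0)
            rng = hi - lo
            if np.any(rng <= 0):
                ch = int(np.argmax(rng <= 0)) + 1
                raise _degenerate(scope, f"participant {key[0]} ({key[1]}) channel {ch}")
        for rec in recs:
            out.append(_build(rec, lo, rng, scope))
    return out


def _build(rec: FMGRecording, lo, rng, scope: str) -> NormalizedRecording:
    return NormalizedRecording(
        signal=(rec.signal - lo) / rng,
        fs=rec.fs,
        participant=rec.participant,
        action=rec.action,
        action_type=rec.action_type,
        placement=rec.placement,
        trial=rec.trial,
        norm_min=lo,
        norm_range=rng,
        scope=scope,
    )
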
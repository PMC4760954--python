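"""Plain-text session bundles.

A session is a directory with three files chosen for diff-ability and
language-agnostic parsing:

``manifest.json``
    session id and the list of unit ids (plus optional metadata per unit).
``trials.tsv``
    one :class:`~seqsel.datatypes.TrialRecord` per row.  Targets are encoded
    ``direction:gamble_id`` joined by ``|``.
``spikes.tsv``
    long format, one spike per row: ``neuron_id  trial_id  spike_time_ms``.

Floats are written with ``repr`` (shortest round-trip representation), so a
read/write cycle is bit-exact.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .datatypes import NeuronData, ParseError, Target, TrialRecord

_TRIAL_COLUMNS = [
    "trial_id",
    "block_id",
    "trial_type",
    "targets",
    "chosen_index",
    "t_fix_on",
    "t_target_on",
    "t_saccade_on",
    "t_outcome",
    "t_reward",
    "reward_delivered",
]


def _fmt(x: float) -> str:
    return repr(float(x))


def _encode_targets(targets: tuple[Target, ...]) -> str:
    return "|".join(f"{_fmt(t.direction)}:{t.gamble_id}" for t in targets)


def _decode_targets(s: str, line: int) -> tuple[Target, ...]:
    out = []
    for part in s.split("|"):
        try:
            d, g = part.split(":")
            out.append(Target(direction=float(d), gamble_id=int(g)))
        except Exception:
            raise ParseError(f"trials.tsv line {line}: bad targets field {part!r}")
    return tuple(out)


def write_session(
    path: str | Path,
    trials: list[TrialRecord],
    neurons: list[NeuronData],
    session_id: str = "session",
) -> Path:
    """Write a session bundle; returns the directory path."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    manifest = {
        "session_id": session_id,
        "units": [
            {"neuron_id": n.neuron_id, "metadata": n.metadata} for n in neurons
        ],
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))

    lines = ["\t".join(_TRIAL_COLUMNS)]
    for tr in trials:
        lines.append(
            "\t".join(
                [
                    str(tr.trial_id),
                    str(tr.block_id),
                    tr.trial_type,
                    _encode_targets(tr.targets),
                    str(tr.chosen_index),
                    _fmt(tr.t_fix_on),
                    _fmt(tr.t_target_on),
                    _fmt(tr.t_saccade_on),
                    _fmt(tr.t_outcome),
                    _fmt(tr.t_reward),
                    _fmt(tr.reward_delivered),
                ]
            )
        )
    (path / "trials.tsv").write_text("\n".join(lines) + "\n")

    lines = ["neuron_id\ttrial_id\tspike_time_ms"]
    for n in neurons:
        for trial_id in sorted(n.spike_times):
            for t in np.asarray(n.spike_times[trial_id]):
                lines.append(f"{n.neuron_id}\t{trial_id}\t{_fmt(t)}")
    (path / "spikes.tsv").write_text("\n".join(lines) + "\n")
    return path


def read_session(path: str | Path) -> tuple[list[TrialRecord], list[NeuronData]]:
    """Read a session bundle, validating every record.

    Raises :class:`ParseError` on malformed fields (naming line and field)
    and :class:`ValidationError` on invariant violations.
    """
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())

    trials: list[TrialRecord] = []
    text = (path / "trials.tsv").read_text().rstrip("\n").split("\n")
    header = text[0].split("\t")
    if header != _TRIAL_COLUMNS:
        raise ParseError(f"trials.tsv: unexpected header {header}")
    for lineno, line in enumerate(text[1:], start=2):
        f = line.split("\t")
        if len(f) != len(_TRIAL_COLUMNS):
            raise ParseError(f"trials.tsv line {lineno}: {len(f)} fields")
        row = dict(zip(_TRIAL_COLUMNS, f))
        try:
            trial = TrialRecord(
                trial_id=int(row["trial_id"]),
                block_id=int(row["block_id"]),
                trial_type=row["trial_type"],
                targets=_decode_targets(row["targets"], lineno),
                chosen_index=int(row["chosen_index"]),
                t_fix_on=float(row["t_fix_on"]),
                t_target_on=float(row["t_target_on"]),
                t_saccade_on=float(row["t_saccade_on"]),
                t_outcome=float(row["t_outcome"]),
                t_reward=float(row["t_reward"]),
                reward_delivered=float(row["reward_delivered"]),
            )
        except ParseError:
            raise
        except ValueError as e:
            # numeric parse failures; invariant breaches re-raise as-is
            from .datatypes import ValidationError

            if isinstance(e, ValidationError):
                raise
            raise ParseError(f"trials.tsv line {lineno}: {e}") from None
        trials.append(trial)

    trial_ids = {t.trial_id for t in trials}
    spikes: dict[int, dict[int, list[float]]] = {
        u["neuron_id"]: {} for u in manifest["units"]
    }
    text = (path / "spikes.tsv").read_text().rstrip("\n").split("\n")
    for lineno, line in enumerate(text[1:], start=2):
        f = line.split("\t")
        if len(f) != 3:
            raise ParseError(f"spikes.tsv line {lineno}: {len(f)} fields")
        try:
            nid, tid, st = int(f[0]), int(f[1]), float(f[2])
        except ValueError as e:
            raise ParseError(f"spikes.tsv line {lineno}: {e}") from None
        if nid not in spikes:
            raise ParseError(f"spikes.tsv line {lineno}: unknown neuron_id {nid}")
        if tid not in trial_ids:
            raise ParseError(f"spikes.tsv line {lineno}: unknown trial_id {tid}")
        spikes[nid].setdefault(tid, []).append(st)

    neurons = []
    for u in manifest["units"]:
        n = NeuronData(
            neuron_id=u["neuron_id"],
            spike_times={
                tid: np.asarray(sts, dtype=float)
                for tid, sts in sorted(spikes[u["neuron_id"]].items())
            },
            metadata=u.get("metadata", {}),
        )
        n.validate()
        neurons.append(n)
    return trials, neurons
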
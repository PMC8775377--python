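"""Packaged example data: the worked office-worker day and cohort records.

The office-worker day (four intakes at 10:00, 14:00, 18:00 and 21:00 with
47.6, 41, 16.3 and 39.7 g of carbohydrate, plus a morning and an evening
walk between desk and domestic blocks) is encoded from its published
narrative description. The 16.3 g snack's absorption split is not stated
and is encoded slow-only; the subject descriptor is synthetic
(cohort-typical assumed values), as its ``note`` field flags.
"""

from __future__ import annotations

import json
from importlib import resources

from .population import ParticipantRecord, VirtualPatient, load_table_records
from .signals import DaySchedule

__all__ = ["participant14_schedule", "participant14_subject", "participant_records"]


def _data(name: str) -> str:
    return resources.files("glycosim.data").joinpath(name).read_text()


def participant14_schedule() -> DaySchedule:
    """The worked single-subject day: 4 meals and 9 activity blocks."""
    return DaySchedule.from_csv(_data("participant14_schedule.csv"))


def participant14_subject() -> VirtualPatient:
    """Synthetic subject descriptor matching the worked day (assumed values)."""
    payload = json.loads(_data("participant14_subject.json"))
    payload.pop("note", None)
    return VirtualPatient(**payload)


def participant_records() -> list[ParticipantRecord]:
    """The 20-person occupation / daily-activity-time table."""
    return load_table_records()
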
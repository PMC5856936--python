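"""Deterministic discrete-event kernel.

A minimal event-calendar simulator: events carry a timestamp in fractional
days and a monotonically increasing scheduling sequence number; the run
loop pops them in ``(time, sequence)`` order, so simultaneous events fire
in the order they were scheduled (stable FIFO).  All stochastic inputs are
sampled outside the kernel; given the same pre-sampled inputs the event
trace is bit-for-bit reproducible, which the trace hash makes checkable.
"""

from __future__ import annotations

import hashlib
import heapq
from dataclasses import dataclass
from typing import Any, Callable

__all__ = ["Event", "EventCalendar", "Simulation", "SchedulingError"]


class SchedulingError(RuntimeError):
    """An event was scheduled or processed out of causal order."""


@dataclass(frozen=True)
class Event:
    time: float
    sequence: int
    kind: str
    payload: Any = None


class EventCalendar:
    """Pending events, extracted in non-decreasing (time, sequence) order."""

    def __init__(self) -> None:
        self._heap: list[tuple[float, int, Event]] = []

    def __len__(self) -> int:
        return len(self._heap)

    def push(self, event: Event) -> None:
        heapq.heappush(self._heap, (event.time, event.sequence, event))

    def peek(self) -> Event:
        return self._heap[0][2]

    def pop(self) -> Event:
        return heapq.heappop(self._heap)[2]


class Simulation:
    """Clock + calendar + handler dispatch.

    Handlers are registered per event kind and receive ``(sim, event)``.
    ``collect_trace=True`` records one line per processed event
    (time, kind, tag) for debugging and for determinism checks.
    """

    def __init__(self, collect_trace: bool = False) -> None:
        self.clock: float = 0.0
        self.calendar = EventCalendar()
        self.handlers: dict[str, Callable[["Simulation", Event], None]] = {}
        self._sequence = 0
        self.collect_trace = collect_trace
        self.trace: list[str] = []

    def on(self, kind: str, handler: Callable[["Simulation", Event], None]) -> None:
        self.handlers[kind] = handler

    def schedule(self, time: float, kind: str, payload: Any = None) -> Event:
        if time < self.clock:
            raise SchedulingError(
                f"cannot schedule {kind!r} at t={time} before clock {self.clock}"
            )
        event = Event(time=float(time), sequence=self._sequence, kind=kind,
                      payload=payload)
        self._sequence += 1
        self.calendar.push(event)
        return event

    def run_until(self, t_end: float) -> None:
        """Process every event with time <= ``t_end``; leave clock at t_end."""
        if t_end < self.clock:
            raise SchedulingError(
                f"t_end {t_end} is before the current clock {self.clock}"
            )
        last = (self.clock, -1)
        while len(self.calendar) and self.calendar.peek().time <= t_end:
            event = self.calendar.pop()
            if (event.time, event.sequence) < last:
                raise SchedulingError("event extracted out of order")  # pragma: no cover
            last = (event.time, event.sequence)
            self.clock = event.time
            if self.collect_trace:
                tag = getattr(event.payload, "case_id", event.payload)
                self.trace.append(f"{event.time:.6f}\t{event.kind}\t{tag}")
            handler = self.handlers.get(event.kind)
            if handler is not None:
                handler(self, event)
        self.clock = t_end

    def trace_hash(self) -> str:
        """SHA-256 of the processed-event trace (requires collect_trace)."""
        digest = hashlib.sha256()
        for line in self.trace:
            digest.update(line.encode())
            digest.update(b"\n")
        return digest.hexdigest()
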
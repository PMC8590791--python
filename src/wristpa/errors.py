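"""Exception hierarchy shared by all pipeline stages."""


class WristpaError(Exception):
    """Base class for all package errors."""


class InputError(WristpaError):
    """Malformed or out-of-contract input data."""


class ConfigError(WristpaError):
    """Inconsistent configuration values."""


class ScheduleError(InputError):
    """Invalid synthetic segment schedule (overlaps, bad durations)."""


class DayOutOfRangeError(InputError):
    """Calendar day falls outside the analyzable measurement days (1-13)."""

    def __init__(self, date, measurement_day):
        self.date = date
        self.measurement_day = measurement_day
        super().__init__(
            f"day {measurement_day} ({date}) is outside measurement days 1-13"
        )
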
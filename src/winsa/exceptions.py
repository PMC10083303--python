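"""Exception hierarchy for the winsa package."""


class WinsaError(Exception):
    """Base class for all package errors."""


class ConfigError(WinsaError):
    """Invalid protocol or cohort configuration."""


class ProtocolError(WinsaError):
    """An agent or session violated the operant-session contract."""


class LogParseError(WinsaError):
    """An event-log file could not be parsed; message names the offending row."""


class ScoringError(WinsaError):
    """Phenotyping could not be completed (missing mandatory sessions, bad input)."""


class StatsError(WinsaError):
    """Statistical routine received input it cannot analyze."""
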
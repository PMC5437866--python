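"""Exception hierarchy shared across the package."""


class SurveyError(Exception):
    """Base class for all surveyerr errors."""


class InputError(SurveyError):
    """Malformed user input (empty names, bad encodings)."""


class ParseError(SurveyError):
    """A file violated its declared schema; message names row and column."""


class DomainError(SurveyError):
    """A precondition on the scientific domain was violated."""


class IntegrityError(SurveyError):
    """Internal consistency violated (duplicate ids, impossible counts)."""


class UndefinedStatisticError(SurveyError):
    """The requested statistic is undefined for this input (e.g. a
    false-positive rate for a survey with no species-rank records)."""
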
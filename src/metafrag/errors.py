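"""Exception hierarchy."""


class MetafragError(Exception):
    """Base class for all package errors."""


class TooFewStudiesError(MetafragError):
    """Pooling requires at least two informative studies."""


class DegenerateStudyError(MetafragError):
    """A study's standard error is non-finite even after continuity correction."""


class NonConvergentScenarioError(MetafragError):
    """The scenario's tau^2 estimator failed to converge on the dataset."""


class CorpusFormatError(MetafragError):
    """The input corpus file violates the long-format schema or a count invariant."""

    def __init__(self, messages):
        if isinstance(messages, str):
            messages = [messages]
        self.messages = list(messages)
        super().__init__("\n".join(self.messages))
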
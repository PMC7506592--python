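"""Package-wide exception types."""


class ErpnatError(Exception):
    """Base class for all erpnat errors."""


class ConfigurationError(ErpnatError):
    """Invalid configuration: bad montage, thresholds, windows, paths."""


class ContractError(ErpnatError):
    """Pipeline stages called out of their fixed order, or on unsuitable input."""


class PipelineError(ErpnatError):
    """A pipeline run could not produce a usable result (e.g. no epochs retained)."""
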
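"""Exception types shared across the package."""


class AdeminerError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(AdeminerError):
    """A mining configuration value is out of its valid range."""


class MeasureUndefinedError(AdeminerError):
    """A rule-strength measure was requested with a zero denominator."""


class UnmappableDrugName(AdeminerError):
    """Drug-string cleanup produced an empty string; caller should keep the raw name."""


class MiningConsistencyError(AdeminerError):
    """A frequent-itemset list violated downward closure; indicates a mining bug."""
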
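"""Exception hierarchy shared by all combipool modules."""


class CombipoolError(Exception):
    """Base class for all combipool-specific errors."""


class DesignInfeasibleError(CombipoolError):
    """A pooling constraint cannot be satisfied (e.g. genus larger than pool count)."""


class CapacityError(CombipoolError):
    """More strains than distinct nonzero signatures available."""


class SchemaError(CombipoolError):
    """An input table references unknown ids or violates its declared schema."""


class UndefinedCorrelationError(CombipoolError):
    """Correlation requested on a zero-variance vector."""
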
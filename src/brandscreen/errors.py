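"""Exception hierarchy for brandscreen.

Every error raised by the library derives from :class:`BrandScreenError`, so
callers (and the CLI) can catch validation problems without swallowing
programming errors.
"""


class BrandScreenError(Exception):
    """Base class for all brandscreen errors."""


class RuleTableError(BrandScreenError):
    """A rule-table config failed schema validation."""


class UnknownCategoryError(BrandScreenError):
    """A product's category code does not resolve in the active rule table."""


class BasisMismatchError(BrandScreenError):
    """Product nutrients and a criterion are declared on different bases.

    No density data is available, so per-100g vs per-100mL is never converted
    silently.
    """


class ClassificationError(BrandScreenError):
    """A product could not be classified for a structural reason."""


class UnclassifiableBrandError(BrandScreenError):
    """A brand with zero classifiable products cannot take a threshold decision."""


class ClickError(BrandScreenError):
    """The leading-product (CLICK) method cannot be applied to a brand."""


class BrandSetMismatchError(BrandScreenError):
    """Two decision sets to be compared do not cover the same brands."""


class SyntheticSpecError(BrandScreenError):
    """A synthetic-data specification is invalid or infeasible."""


class ProductTableError(BrandScreenError):
    """A product (or metadata) table failed validation on read."""
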
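"""Exception hierarchy for the cycloperm pipeline."""


class CyclopermError(Exception):
    """Base class for all package errors."""


class InputError(CyclopermError):
    """Malformed or unparsable user input (SMILES, CSV, config values)."""


class SizeError(CyclopermError):
    """An input exceeds a configured size bound."""


class DivisionError(CyclopermError):
    """The macrocycle could not be divided into monomers."""


class ChemistryError(CyclopermError):
    """A chemical operation produced an invalid (e.g. valence-violating) result."""


class ConformerError(CyclopermError):
    """3D embedding failed after the configured number of retries."""


class DescriptorError(CyclopermError):
    """A molecular descriptor could not be computed."""


class FitError(CyclopermError):
    """Fitting a statistical component (standardizer, selector) failed."""


class SelectionError(CyclopermError):
    """Descriptor selection could not satisfy the request."""


class DegeneracyError(CyclopermError):
    """Two distinct real atoms coincide (zero interatomic distance)."""


class ConfigError(CyclopermError):
    """Invalid run configuration."""
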
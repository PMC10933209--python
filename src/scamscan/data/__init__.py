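"""Bundled synthetic example data.

The compound table shipped here is *synthetic*: apart from a few
published single values noted in its header comments, descriptors and
MD fC_5 numbers are invented to exercise the screening workflow with a
realistic 32-compound error structure.
"""

from importlib import resources
from pathlib import Path


def synthetic_compound_table_path() -> Path:
    """Path to the bundled synthetic 32-compound descriptor CSV."""
    return Path(resources.files(__package__) / "synthetic_compounds.csv")
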
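"""Bundled and user-supplied network definitions.

The 81-node acute promyelocytic leukemia (APL) endogenous network (8
functional modules, 416 signed interactions) is published as supplementary
material alongside its 81 rate equations; it is not redistributed here.
Place a transcription in the TSV dialect at the path returned by
:func:`apl_network_path` to unlock the APL-specific analyses (attractor
census S1-S18, induced switching protocols, saddle-mediated routes).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .network import Network, parse_network

APL_FILENAME = "apl_network.tsv"


def apl_network_path() -> Path:
    """Expected location of the user-supplied APL network transcription."""
    return Path(str(resources.files("endonet.data"))) / APL_FILENAME


def load_apl_network() -> Network:
    """Load the 81-node APL network transcription, if installed.

    Raises FileNotFoundError with instructions when the transcription is
    absent.
    """
    path = apl_network_path()
    if not path.exists():
        raise FileNotFoundError(
            f"APL network transcription not found at {path}. Transcribe the "
            "published 81-node / 416-interaction network into the TSV "
            "dialect (see the network module docs) and place it there.")
    return parse_network(path.read_text(), dialect="tsv")
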
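"""Bundled reference data: the published demosponge bona fide miRNA set.

The table lists the 30 mature miRNAs reported for the two Red Sea
demosponges — 11 from *Stylissa carteri* ("sca") and 19 from *Xestospongia
testudinaria* ("xte") — with their matches to previously known
*Amphimedon queenslandica* ("aqu") miRNA families where one exists.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import pandas as pd

from .conserve import MatureMiRNA
from .errors import DataError

_TABLE2_SHA256 = "44594b822dc1eabf15d67745fe802023cb6a79c0f563fcc81273be8dd21d4fed"


def _table2_bytes() -> bytes:
    return (resources.files("spongemir") / "data" / "table2.tsv").read_bytes()


def load_table2_fixture() -> list[MatureMiRNA]:
    """The 30 demosponge bona fide matures (11 sca + 19 xte), RNA alphabet.

    The bundled file is checksum-verified; a corrupted bundle raises
    :class:`DataError`.
    """
    raw = _table2_bytes()
    if hashlib.sha256(raw).hexdigest() != _TABLE2_SHA256:
        raise DataError("bundled mature-miRNA table failed its integrity check")
    from io import BytesIO

    df = pd.read_csv(BytesIO(raw), sep="\t").fillna({"known_match": ""})
    return [MatureMiRNA(name=row.name_, species=row.species,
                        mature_seq=row.mature_seq, known_match=row.known_match)
            for row in df.rename(columns={"name": "name_"}).itertuples(index=False)]


def table2_frame() -> pd.DataFrame:
    """The same fixture as a DataFrame (name, species, mature_seq, known_match)."""
    from io import BytesIO

    return pd.read_csv(BytesIO(_table2_bytes()), sep="\t").fillna({"known_match": ""})


__all__ = ["load_table2_fixture", "table2_frame"]
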
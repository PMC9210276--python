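"""Packaged 30-aa domain-marker peptides.

These are fixed synthetic signature peptides standing in for the conserved
domains of tyrosine-recombinase retrotransposons (gag, reverse transcriptase,
RNase H, DAM-methyltransferase, tyrosine recombinase, SGNH hydrolase), so that
domain scanning works offline without a conserved-domain database.  Each
peptide carries a flavour of the real motif (the RT marker contains the
canonical YxDD box, the YR marker the catalytic tyrosine triad context, the
SGNH marker its four namesake residues) but the peptides as a whole are
synthetic and are used both by the generator (written into ORFs) and by the
scanner (queried against translated ORFs).
"""

from __future__ import annotations

#: marker label -> 30-aa synthetic signature peptide
MARKERS: dict[str, str] = {
    "GAG": "MQPRNAKELCWTGSPFVNKQAYLDRIMPGE",
    "RT": "KLPQGFVLSPYLFNIVMDELTRGIQWHADD",
    "RH": "AYADDLVLFSEGKHIEDQLTRCFEWAGRNN",
    "MT": "DPFCGSGTTLVEAQNLGRHFIGSDINEKAV",
    "YR": "GLRASELLDLRVKDVHFERGVIHIRETKFG",
    "SGNH": "VIMSLGANDAINRQPVDEWKSNLREMIGHA",
}

#: expected marker order along a DIRS-like element (gag, RT/RH(/MT), YR)
DIRS_DOMAIN_ORDER = ("GAG", "RT", "RH", "MT", "YR")
#: expected marker order along a Ngaro-like element (gag, RT/RH, YR, SGNH)
NGARO_DOMAIN_ORDER = ("GAG", "RT", "RH", "YR", "SGNH")

MARKER_LENGTH = 30

for _label, _pep in MARKERS.items():
    assert len(_pep) == MARKER_LENGTH, _label
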
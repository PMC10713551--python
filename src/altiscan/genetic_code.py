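"""Standard genetic code (codon -> one-letter amino acid, '*' = stop)."""

from Bio.Data import CodonTable as _CT

_standard = _CT.unambiguous_dna_by_id[1]

CODON_TABLE: dict[str, str] = dict(_standard.forward_table)
for _stop in _standard.stop_codons:
    CODON_TABLE[_stop] = "*"
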
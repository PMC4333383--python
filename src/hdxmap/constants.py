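"""Physical constants shared across the package.

All masses are in daltons (Da). Values follow the conventions used by
mainstream HDX-MS processing software.
"""

#: Mass added to a neutral molecule per positive charge (proton mass).
PROTON_MASS = 1.00728

#: Mass difference between deuterium and protium; one incorporated deuteron
#: shifts a peptide's neutral mass by this amount.
DH_MASS_DIFF = 1.00628

#: Average spacing between adjacent aggregated isotopologue peaks of a
#: peptide.  Dominated by the 13C-12C difference; configurable where used.
ISOTOPE_SPACING = 1.00235

#: One-letter codes of the twenty standard amino acids.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
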
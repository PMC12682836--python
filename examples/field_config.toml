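# Example reader configuration for a field survey table.
#
# The `role` column in the leaf table decides which rows anchor each site:
#   positive_ref — a co-occurring known carboxylate exuder. Cluster-rooted
#                  Proteaceae (Banksia) are the usual choice; Persoonia is a
#                  workable substitute where Banksia is absent.
#   negative_ref — a co-occurring non-exuder: Xanthorrhoea where present,
#                  otherwise Acacia or Macrozamia, or young eucalypt leaves
#                  (set leaf_age = "young"; Mn accumulates only with leaf age).
# Sites with no usable reference of one polarity automatically fall back to
# the cross-site average reference (APR/ANR), flagged in all outputs.

[columns]
site_id = "site_id"
region = "region"
species = "species"
genus = "genus"
role = "role"
replicate = "replicate"
leaf_age = "leaf_age"

# element symbol -> column header in the file
[elements]
N = "N"
P = "P"
K = "K"
Ca = "Ca"
Cu = "Cu"
Zn = "Zn"
Mn = "Mn"
Fe = "Fe"
Mg = "Mg"

# declared units per element; readers convert into the canonical scale
# (N, P in mg_g; K, Ca, Cu, Zn, Mn, Fe, Mg in mg_kg)
[units]
N = "mg_g"
P = "mg_g"
Mn = "mg_kg"

# taxon synonym map applied after whitespace/underscore normalisation;
# name revisions are the user's responsibility (no fuzzy matching)
[aliases]
"Eucalyptus signata" = "Eucalyptus racemosa"
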
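# Interaction detection method conversion table.
# Two columns, tab-separated: PSI-MI detection-method code -> method category.
# Technically similar assays share one category so that the Method Score
# counts distinct technique families, not raw ontology codes.
# Grouping reconstructed at assay-family level from the PSI-MI ontology
# detection-method branch.
MI:0018	Two Hybrid (2Hyb)
MI:0397	Two Hybrid (2Hyb)
MI:0398	Two Hybrid (2Hyb)
MI:0399	Two Hybrid (2Hyb)
MI:0727	Two Hybrid (2Hyb)
MI:0728	Two Hybrid (2Hyb)
MI:1112	Two Hybrid (2Hyb)
MI:1113	Two Hybrid (2Hyb)
MI:0004	Affinity Purification (AP)
MI:0006	Affinity Purification (AP)
MI:0007	Affinity Purification (AP)
MI:0019	Affinity Purification (AP)
MI:0096	Affinity Purification (AP)
MI:0676	Affinity Purification (AP)
MI:0090	Complementation Assay (PCA)
MI:0111	Complementation Assay (PCA)
MI:0232	Complementation Assay (PCA)
MI:0809	Complementation Assay (PCA)
MI:0030	Cross-linking (XL)
MI:0031	Cross-linking (XL)
MI:0012	Resonance Energy Transfer (RET)
MI:0055	Resonance Energy Transfer (RET)
MI:0416	Imaging (Img)
MI:0663	Imaging (Img)
MI:0013	Biophysical (Bioph)
MI:0017	Biophysical (Bioph)
MI:0065	Biophysical (Bioph)
MI:0107	Biophysical (Bioph)
MI:0077	Structure (Struct)
MI:0114	Structure (Struct)
MI:0415	Enzymatic Assay (Enz)
MI:0424	Enzymatic Assay (Enz)
MI:0008	Protein Array (Array)
MI:0089	Protein Array (Array)
MI:0084	Display (Disp)
MI:0045	Unspecified (Unspec)
MI:0686	Unspecified (Unspec)
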
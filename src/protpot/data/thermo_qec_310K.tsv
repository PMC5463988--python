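# Standard Gibbs energies for the QEC+ basis and polypeptide residue groups.
# Evaluation condition: 310.15 K, 1 bar.  ESTIMATED values; see
# scripts/build_thermo_table.py and docs/methods.md for the derivation
# and stated uncertainty.  Regenerate: python scripts/build_thermo_table.py
species	kind	formula	G0_Jmol	source
Cys	basis	C3H7NO2S	-339800.0	aqueous cysteine; recalled compilation value; consistent with Ser + (OH->SH)
Glu	basis	C5H9NO4	-724870.0	aqueous glutamic acid; increment: Ala + CH2 + COOH; matches recalled -723.8
Gln	basis	C5H10N2O3	-528870.0	aqueous glutamine; cycle: Glu + amidation calibrated to glutamine hydrolysis ~ -14 kJ/mol
H2O	basis	H2O	-237140.0	liquid water, CODATA
O2	basis	O2	0.0	gaseous O2, element reference state
H+	basis	H+1	0.0	aqueous proton, zero by convention
Ala	residue	C3H5NO	-122160.0	free AA - H2O + 12 kJ/mol peptide term; AA: anchor: widely reproduced aqueous value
Arg	residue	C6H12N4O	9140.0	free AA - H2O + 12 kJ/mol peptide term; AA: recalled compilation ballpark (guanidino); low confidence
Asn	residue	C4H6N2O2	-288330.0	free AA - H2O + 12 kJ/mol peptide term; AA: cycle: Asp + amidation (glutamine-hydrolysis cycle)
Asp	residue	C4H5NO3	-484330.0	free AA - H2O + 12 kJ/mol peptide term; AA: increment: Ala with H->COOH (acetic acid/methane)
Cys	residue	C3H5NOS	-90660.0	free AA - H2O + 12 kJ/mol peptide term; AA: recalled compilation value; consistent with Ser + (OH->SH)
Gln	residue	C5H8N2O2	-279730.0	free AA - H2O + 12 kJ/mol peptide term; AA: cycle: Glu + amidation calibrated to glutamine hydrolysis ~ -14 kJ/mol
Glu	residue	C5H7NO3	-475730.0	free AA - H2O + 12 kJ/mol peptide term; AA: increment: Ala + CH2 + COOH; matches recalled -723.8
Gly	residue	C2H3NO	-130760.0	free AA - H2O + 12 kJ/mol peptide term; AA: anchor: widely reproduced aqueous value
His	residue	C6H7N3O	28940.0	free AA - H2O + 12 kJ/mol peptide term; AA: recalled compilation ballpark (imidazole); low confidence
Ile	residue	C6H11NO	-94760.0	free AA - H2O + 12 kJ/mol peptide term; AA: increment: Leu + branching correction
Leu	residue	C6H11NO	-96360.0	free AA - H2O + 12 kJ/mol peptide term; AA: increment: Ala + 3 CH2
Lys	residue	C6H12N2O	-41160.0	free AA - H2O + 12 kJ/mol peptide term; AA: increment: Ala + 3 CH2 + (H->NH2 from methylamine/methane); low confidence
Met	residue	C5H9NOS	-81860.0	free AA - H2O + 12 kJ/mol peptide term; AA: increment estimate: thioether side chain; low confidence
Phe	residue	C9H9NO	37440.0	free AA - H2O + 12 kJ/mol peptide term; AA: recalled compilation value; consistent with toluene-based increment
Pro	residue	C5H7NO	-55860.0	free AA - H2O + 12 kJ/mol peptide term; AA: recalled compilation value (cyclic imino acid); low confidence
Ser	residue	C3H5NO2	-263140.0	free AA - H2O + 12 kJ/mol peptide term; AA: increment: Ala with H->OH (methanol/methane)
Thr	residue	C4H7NO2	-254540.0	free AA - H2O + 12 kJ/mol peptide term; AA: increment: Ser + CH2
Trp	residue	C11H10N2O	137040.0	free AA - H2O + 12 kJ/mol peptide term; AA: recalled compilation ballpark (indole); low confidence
Tyr	residue	C9H9NO2	-136360.0	free AA - H2O + 12 kJ/mol peptide term; AA: recalled compilation value; phenol-based increment gives -396
Val	residue	C5H9NO	-104960.0	free AA - H2O + 12 kJ/mol peptide term; AA: increment: Ala + 2 CH2
terminus	terminus	H2O	-237140.0	chain terminus group (composition H2O), set to liquid water
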
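rule_name	delta_formula	sign
hydrogenation	H2	+
dehydrogenation	H2	-
methylation	CH2	+
demethylation	CH2	-
oxidation	O	+
deoxygenation	O	-
hydration	H2O	+
dehydration	H2O	-
amination	NH3	+
deamination	NH3	-
carbonylation	CO	+
decarbonylation	CO	-
carboxylation	CO2	+
decarboxylation	CO2	-
acetylation	C2H2O	+
deacetylation	C2H2O	-
sulfation	SO3	+
desulfation	SO3	-
glucuronidation	C6H8O6	+
deglucuronidation	C6H8O6	-
ethylation	C2H4	+
deethylation	C2H4	-
phosphorylation	HPO3	+
dephosphorylation	HPO3	-
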
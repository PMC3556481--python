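patient_id	histology	ER	PR	HER2	MUC1_16A
1	IDC+ILC	+	+	-	+
2	IDC	+	-	+	-
3	IDC	+	-	-	-
4	IDC	+	-	+	+
5	IDC	+	+	+	+
6	IDC	-	-	-	-
7	IDC	+	-	-	+
8	IDC	+	-	-	-
9	IDC	+	-	+	-
10	IDC	-	-	-	-
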
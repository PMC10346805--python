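# Published per-center excess charges (e) for the five pentapeptides;
# labels keep the original per-structure lettering.
peptide	label	charge_e
CIHNP	a	-0.70
CIHNP	b	-0.58
CIHNP	c	-0.61
CIHNP	d	-0.59
CIHNP	e	-0.59
CIHNP	f	-0.27
CIHNP	g	-0.58
CIHNP	h	-0.10
CRQVF	a	-0.41
CRQVF	b	-0.59
CRQVF	c	-0.56
CRQVF	d	-0.59
CRQVF	e	-0.58
CRQVF	f	-0.60
CRQVF	g	-0.36
CRQVF	h	-0.56
DNPIQAVP	a	-0.39
DNPIQAVP	b	-0.28
DNPIQAVP	c	-0.28
DNPIQAVP	d	-0.60
DNPIQAVP	e	-0.57
DNPIQAVP	f	-0.66
DNPIQAVP	g	-0.38
DNPIQAVP	h	-0.63
DSWAADIP	a	-0.37
DSWAADIP	b	-0.29
DSWAADIP	c	-0.38
DSWAADIP	d	-0.60
DSWAADIP	e	-0.60
DSWAADIP	f	-0.55
DSWAADIP	g	-0.40
DSWAADIP	h	-0.58
WHVSC	a	-0.41
WHVSC	b	-0.57
WHVSC	c	-0.56
WHVSC	d	-0.54
WHVSC	e	-0.60
WHVSC	f	-0.60
WHVSC	g	-0.55
WHVSC	h	-0.47
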
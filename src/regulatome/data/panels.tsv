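panel	subgroup	gene_symbol
housekeeping		CHMP2A
housekeeping		PSMB4
housekeeping		ACTB
housekeeping		GAPDH
redox	ROS-generating	XDH
redox	ROS-generating	NOX1
redox	ROS-generating	NOX3
redox	ROS-generating	NOX4
redox	ROS-generating	NOX5
redox	ROS-generating	NOS1
redox	ROS-generating	NOS2
redox	ROS-generating	NOS3
redox	ROS-generating	MPO
redox	antioxidant	GPX1
redox	antioxidant	GPX2
redox	antioxidant	GPX3
redox	antioxidant	GPX4
redox	antioxidant	GPX5
redox	antioxidant	GPX6
redox	antioxidant	GPX7
redox	antioxidant	GPX8
redox	antioxidant	GSR
redox	antioxidant	CAT
redox	antioxidant	SOD1
redox	antioxidant	SOD2
redox	antioxidant	SOD3
chromatin_factors	insulator-binding	CTCF
chromatin_factors	insulator-binding	RAD21
chromatin_factors	promoter-binding	POLR3A
chromatin_factors	promoter-binding	POLR3B
chromatin_factors	promoter-binding	POLR3C
chromatin_factors	promoter-binding	POLR3D
chromatin_factors	promoter-binding	POLR3E
chromatin_factors	promoter-binding	POLR3F
chromatin_factors	promoter-binding	POLR3G
chromatin_factors	promoter-binding	POLR3H
chromatin_factors	promoter-binding	GTF3C1
chromatin_factors	promoter-binding	GTF3C2
chromatin_factors	promoter-binding	GTF3C3
chromatin_factors	promoter-binding	GTF3C4
chromatin_factors	promoter-binding	GTF3C5
chromatin_factors	promoter-binding	BRF1
chromatin_factors	promoter-binding	BDP1
chromatin_factors	promoter-binding	E2F4
chromatin_factors	non-promoter-binding	JUN
chromatin_factors	non-promoter-binding	GATA1
chromatin_factors	non-promoter-binding	GATA2
chromatin_factors	non-promoter-binding	SMARCB1
chromatin_factors	non-promoter-binding	SMARCA4
chromatin_factors	non-promoter-binding	SIRT6
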
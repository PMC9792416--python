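# name=RG9(synthetic)
# note=synthetic stand-in for an RG9-class far-red long-pass; not manufacturer data
# columns=wavelength_nm transmission_fraction
640.0	0.000000
645.0	0.000000
650.0	0.000000
655.0	0.000000
660.0	0.000000
665.0	0.000000
670.0	0.000000
675.0	0.000000
680.0	0.001696
685.0	0.005890
690.0	0.020220
695.0	0.066755
700.0	0.195976
705.0	0.440000
710.0	0.684024
715.0	0.813245
720.0	0.859780
725.0	0.874110
730.0	0.878304
735.0	0.879514
740.0	0.879861
745.0	0.879960
750.0	0.879989
755.0	0.879997
760.0	0.879999
765.0	0.880000
770.0	0.880000
775.0	0.880000
780.0	0.880000
785.0	0.880000
790.0	0.880000
795.0	0.880000
800.0	0.880000
805.0	0.880000
810.0	0.880000
815.0	0.880000
820.0	0.880000
825.0	0.880000
830.0	0.880000
835.0	0.880000
840.0	0.880000
845.0	0.880000
850.0	0.880000
855.0	0.880000
860.0	0.880000
865.0	0.880000
870.0	0.880000
875.0	0.880000
880.0	0.880000
885.0	0.880000
890.0	0.880000
895.0	0.880000
900.0	0.880000
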
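>GAG_Tekay|GAG|Gypsy|Tekay
LFQTCMLWIEGRAWYIVTCQTFQSLSRLVNGPAMKLISLHAHQPLQSGRKCEHEIYCVAW
QNKKDDWNKGAIDVTVKAWWNSQNYKVEPNDPCHIMEEGDITFYPYYIPAKYVTMIVEWH
>AP_Tekay|AP|Gypsy|Tekay
SICVHNVSSIKWCYCAMQWQMNRNFWLLKGMATEVYFYHTVFTVKYRNIEGFLQFKSRET
FSYFAMRDSEQCKDTWGRYDYECRYFRDLT
>INT_Tekay|INT|Gypsy|Tekay
QMIFGHELFQQRRCQKCSPMIPARTFCFFYIKLPWVCVINETWKQNHCFECSRHHTEERF
NIAKNAYFADHMWVQTGQWNKEDASGQHHYFENDMLIGQSGRRCCDAQAKDMVFWHWRNY
HWHPLPYHKN
>RT_Tekay|RT|Gypsy|Tekay
SKWYKQVLVHHGWLINKWHKYVHFWNSHIHTMEHEQNYRDPLRHVLNKLFPTHMWFCVQF
QDHICGLRIYLARNMRIDHIFKVYALDAWTAGMGKDQDPNQTEPLMNGPHDGDHAIPQQD
EETCRTNNNARWPSDACKCPLRSSQFFIEF
>RH_Tekay|RH|Gypsy|Tekay
AMAKTDNNKPHVFLVSQTFQWASTSLKFNEPIYNEPMSQQALPWWNQTHVECYQENLHHQ
SEWHMCMGDRASRRFMSFITTYWKHRAWDYPEEQYKEEGSYSFMEHNAHI
>GAG_Ivana|GAG|Copia|Ivana
PCRIAPVDYMTLKAPFLAQRMKSGNIRCTYRNCQFWKQKPDIEGPDSDMQETVDCYFMRC
CVTFCSLFIETVFLIGGDPCMWEHGKYFYRTRHHHAIQEYADKIWTLRSCLKVFDWAFAR
>AP_Ivana|AP|Copia|Ivana
PWTNKICKEPAPHICPYMRDIDRYMNLSYLPMYENLHQRAVMFAPYSFLECKIKEWCVWY
FWPMLLIHFDRPPKTPHLWGPEHKTSPKNL
>INT_Ivana|INT|Copia|Ivana
CMKRDIFQCGVWWNMISYDHEIDEALQTTAIELPCQIWIKHTWFECMGKCWGGYMFCCLE
HGYSLMWVIKAYICYKKINSLQECYEYYSWDPDMDLYGKDQQIYFRKGDFCLNWQQIPEW
WPFWARDAEA
>RT_Ivana|RT|Copia|Ivana
FFYPYMPMTECEHAESQNCAEVAQCEPRDCLDVRMMICNWVWTFGRMEPFDKRDVAQEGY
MFGMLYSSQLYKFDGQKFQGPYAPDTEIFPRRVRDTKWGRGTYCYQLNFFHAYYNDMCCK
PHAMIAWCSKREPNITSKYDFEWVAGYITY
>RH_Ivana|RH|Copia|Ivana
PSVINRGDQLFYERFVSLNPPGENGFMFHFWIMAWNGRKNRNKERLQKGNMHILNHCVPD
QKSACSTAFYVTKGGALLPMHEMPWEYDYKAVYDRDYDHGAPKFYQIFKP
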
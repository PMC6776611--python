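<?xml version='1.0' encoding='utf-8'?>
<odML version="1.4">
  <author>Alice</author>
  <date>2000-01-01</date>
  <version>1.0</version>
  <section>
    <name>Subject</name>
    <type>subject</type>
    <id>5698df91-2db0-47ed-a712-407ef1a378cd</id>
    <section>
      <name>Scores_2000-01-01</name>
      <type>scores</type>
      <id>8c6451da-5c37-4b2d-94f7-7e61d4fc4b55</id>
      <property>
        <name>Date</name>
        <type>date</type>
        <value>2000-01-01</value>
        <id>89163033-07cd-48f1-9c44-08d74e10ad22</id>
      </property>
      <property>
        <name>Weight</name>
        <unit>g</unit>
        <type>float</type>
        <value>5.0</value>
        <id>5211e6c3-d775-4e77-aa7f-f8ee64c3dc7f</id>
      </property>
      <property>
        <name>Experimenter</name>
        <type>string</type>
        <value>Alice</value>
        <id>dd4f0451-4517-475d-bb87-777a15a545dc</id>
      </property>
      <property>
        <name>Comment</name>
        <type>text</type>
        <value>Blood sample was taken [...]</value>
        <id>ccb1510c-9836-4f47-848a-ef4756d05ae2</id>
      </property>
    </section>
    <section>
      <name>Scores_2000-01-02</name>
      <type>scores</type>
      <id>c6f98077-c232-4c3b-a0e7-29657c3c064a</id>
      <property>
        <name>Date</name>
        <type>date</type>
        <value>2000-01-02</value>
        <id>9de4a636-6833-4bea-9a5a-111393f9ddd0</id>
      </property>
      <property>
        <name>Weight</name>
        <unit>g</unit>
        <type>float</type>
        <value>5.5</value>
        <id>55cdb427-1725-4c6f-a80b-e9b43d1c4ec7</id>
      </property>
      <property>
        <name>Experimenter</name>
        <type>string</type>
        <value>Bob</value>
        <id>a1e3b792-d80b-49c1-b63f-a1827fd2f95f</id>
      </property>
      <property>
        <name>Comment</name>
        <type>text</type>
        <value>Small scratch at the right ear</value>
        <id>65e07dcf-0356-40cb-8c6d-7c39e0c65913</id>
      </property>
    </section>
  </section>
</odML>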